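"""Sampling-effort regression.

Delimitation tends to split heavily sampled species more often, simply
because a species cannot be split into more groups than it has specimens.
To quantify that bias, the number of delimited groups per species is
regressed on the number of sampled specimens of that species.  Only species
classified MATCH or SPLIT contribute points: singletons are excluded (they
cannot be split, biasing toward matches) and merged/complexed species have
no well-defined group count of their own.

The fit is ordinary least squares with the slope's F-test on (1, n-2)
degrees of freedom, the layout of standard spreadsheet regression output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy import stats

from .congruence import CongruenceRecord
from .haplotypes import HaplotypeMap
from .io_formats import Partition

__all__ = ["RegressionResult", "delimitation_points", "ols_fit", "leave_one_out_r2"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    n: int
    mean_x: float
    se_mean_x: float


def delimitation_points(
    p: Partition,
    labels: Mapping[str, str | None],
    classification: Mapping[str, CongruenceRecord],
    haplotype_map: HaplotypeMap | None = None,
) -> list[tuple[str, int, int]]:
    """(species, n_samples, n_groups) points for the sampling regression.

    ``n_samples`` counts specimens in the full pre-collapse dataset when a
    haplotype map is supplied (each kept haplotype contributes its
    multiplicity), otherwise sequences in the analysed dataset.
    """
    points: list[tuple[str, int, int]] = []
    for species in sorted(classification):
        rec = classification[species]
        if rec.category not in ("MATCH", "SPLIT"):
            continue
        member_ids = [
            seq_id
            for seq_id, sp in labels.items()
            if sp == species and seq_id in p.assignment
        ]
        if haplotype_map is not None:
            n_samples = sum(
                haplotype_map.multiplicity(seq_id)
                if seq_id in haplotype_map.represents
                else 1
                for seq_id in member_ids
            )
        else:
            n_samples = len(member_ids)
        points.append((species, n_samples, rec.n_clusters_touched))
    if not points:
        raise ValueError("no MATCH or SPLIT species: nothing to regress")
    return points


def ols_fit(points: list[tuple]) -> RegressionResult:
    """OLS of group count on sample count with the slope's F-test.

    Accepts (species, x, y) or bare (x, y) tuples.
    """
    xy = [(pt[-2], pt[-1]) for pt in points]
    n = len(xy)
    if n < 3:
        raise ValueError("need at least 3 points")
    x = [float(a) for a, _ in xy]
    y = [float(b) for _, b in xy]
    if len(set(x)) == 1:
        raise ValueError("x is constant: slope undefined")
    mean_x = sum(x) / n
    var_x = sum((v - mean_x) ** 2 for v in x) / (n - 1)
    if len(set(y)) == 1:  # flat response: vacuous fit
        return RegressionResult(
            slope=0.0, intercept=y[0], F=0.0, df=(1, n - 2), p_value=1.0,
            r_squared=0.0, n=n, mean_x=mean_x, se_mean_x=math.sqrt(var_x / n),
        )
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    if 1.0 - r2 <= 0.0:
        f_stat = math.inf
        p_value = 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p_value = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        F=float(f_stat),
        df=(1, n - 2),
        p_value=p_value,
        r_squared=float(r2),
        n=n,
        mean_x=mean_x,
        se_mean_x=math.sqrt(var_x / n),
    )


def leave_one_out_r2(points: list[tuple]) -> list[tuple[str, float]]:
    """r² after removing each point in turn (outlier influence check)."""
    if len(points) < 4:
        raise ValueError("need at least 4 points for leave-one-out")
    out = []
    for i, pt in enumerate(points):
        rest = points[:i] + points[i + 1 :]
        name = pt[0] if len(pt) == 3 else str(i)
        try:
            out.append((name, ols_fit(rest).r_squared))
        except ValueError:
            out.append((name, math.nan))
    return out
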