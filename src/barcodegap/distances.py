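"""Pairwise evolutionary distances and barcode-gap summaries.

Distances are computed under pairwise deletion: for each sequence pair only
the columns where both records carry an unambiguous base (A/C/G/T) are
compared; gaps, N and IUPAC ambiguity codes are treated as missing data for
that pair.  Three models are available:

* ``p``   — uncorrected proportion of differing sites;
* ``K2P`` — Kimura two-parameter correction,
  d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),
  where P and Q are the transition and transversion proportions;
* ``TN93`` — Tamura–Nei correction with empirical base frequencies and
  separate purine/pyrimidine transition rates; reduces to K2P when the
  four frequencies are equal and the two transition classes balance.

Saturated pairs (a logarithm argument ≤ 0) or pairs with no comparable
sites yield NaN, flagged as "undefined" rather than raising, so a single
bad pair cannot abort a whole-matrix computation.  Distances are stored as
substitutions/site proportions; per-species summaries support the standard
curation reports (minimum interspecific distance below a cutoff, maximum
intraspecific distance above a cutoff) and MEGA-style bootstrap standard
errors obtained by resampling alignment columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import Alignment, SequenceRecord

__all__ = [
    "SiteCounts",
    "DistanceMatrix",
    "SpeciesSummary",
    "site_counts",
    "k2p",
    "tn93",
    "p_distance",
    "distance_matrix",
    "species_summaries",
    "low_interspecific_pairs",
    "high_intraspecific_species",
    "bootstrap_se",
    "mean_intraspecific",
]

logger = logging.getLogger(__name__)

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASES.get(ch, -1) for ch in seq], dtype=np.int8)


@dataclass(frozen=True)
class SiteCounts:
    """Per-pair site comparison tallies (pairwise deletion).

    P1/P2 split the transitions into purine (A<->G) and pyrimidine (C<->T)
    classes; ``freqs`` are the empirical base frequencies over the compared
    sites of both sequences, in A, C, G, T order.
    """

    L: int
    P1: float
    P2: float
    Q: float
    freqs: tuple[float, float, float, float]

    @property
    def P(self) -> float:
        return self.P1 + self.P2


def _site_counts_coded(a: np.ndarray, b: np.ndarray) -> SiteCounts:
    both = (a >= 0) & (b >= 0)
    L = int(both.sum())
    if L == 0:
        return SiteCounts(0, 0.0, 0.0, 0.0, (0.25, 0.25, 0.25, 0.25))
    aa, bb = a[both], b[both]
    diff = aa != bb
    lo = np.minimum(aa, bb)[diff]
    hi = np.maximum(aa, bb)[diff]
    ts_pur = int(np.sum((lo == 0) & (hi == 2)))  # A<->G
    ts_pyr = int(np.sum((lo == 1) & (hi == 3)))  # C<->T
    q = int(diff.sum()) - ts_pur - ts_pyr
    counts = np.bincount(aa, minlength=4) + np.bincount(bb, minlength=4)
    freqs = tuple((counts / counts.sum()).tolist())
    return SiteCounts(L, ts_pur / L, ts_pyr / L, q / L, freqs)


def site_counts(a: SequenceRecord, b: SequenceRecord) -> SiteCounts:
    """Tally compared sites, transitions and transversions for one pair."""
    if len(a.seq) != len(b.seq):
        raise ValueError("sequences must have equal aligned length")
    return _site_counts_coded(_encode(a.seq), _encode(b.seq))


def k2p(c: SiteCounts) -> float:
    """Kimura two-parameter distance; NaN when saturated or L == 0."""
    if c.L == 0:
        return math.nan
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def tn93(c: SiteCounts) -> float:
    """Tamura–Nei (1993) distance with empirical frequencies.

    NaN when saturated, when L == 0, or when any base class is absent
    (the correction is then undefined).
    """
    if c.L == 0:
        return math.nan
    ga, gc, gg, gt = c.freqs
    gr, gy = ga + gg, gc + gt
    if min(ga, gc, gg, gt) <= 0.0:
        # degenerate composition: no purine or pyrimidine class to correct
        return math.nan if (c.P1 or c.P2 or c.Q) else 0.0
    k1 = 2.0 * ga * gg / gr
    k2 = 2.0 * gt * gc / gy
    k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)
    w1 = 1.0 - c.P1 / k1 - c.Q / (2.0 * gr)
    w2 = 1.0 - c.P2 / k2 - c.Q / (2.0 * gy)
    w3 = 1.0 - c.Q / (2.0 * gr * gy)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def p_distance(c: SiteCounts) -> float:
    """Uncorrected proportion of differing compared sites."""
    if c.L == 0:
        return math.nan
    return c.P + c.Q


_MODELS: dict[str, Callable[[SiteCounts], float]] = {
    "p": p_distance,
    "K2P": k2p,
    "TN93": tn93,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; NaN entries are undefined."""

    ids: list[str]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.index = {seq_id: i for i, seq_id in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index[id_a], self.index[id_b]])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.d[iu]).sum())

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self.index[i] for i in ids]
        return DistanceMatrix(ids, self.d[np.ix_(idx, idx)].copy(), self.model)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, seq_id in enumerate(self.ids):
                row = " ".join(
                    "NA" if np.isnan(v) else f"{v:.6f}" for v in self.d[i]
                )
                fh.write(f"{seq_id}  {row}\n")

    def write_lower_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, seq_id in enumerate(self.ids):
                cells = [
                    "NA" if np.isnan(self.d[i, j]) else f"{self.d[i, j]:.6f}"
                    for j in range(i)
                ]
                fh.write("\t".join([seq_id] + cells) + "\n")


def distance_matrix(aln: Alignment, model: str = "K2P") -> DistanceMatrix:
    """All-pairs distance matrix under the chosen model."""
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    fn = _MODELS[model]
    n = len(aln)
    codes = [_encode(r.seq) for r in aln]
    d = np.zeros((n, n))
    undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            v = fn(_site_counts_coded(codes[i], codes[j]))
            d[i, j] = d[j, i] = v
            if math.isnan(v):
                undefined += 1
    if undefined:
        logger.warning("%d undefined (saturated/no-overlap) pairs flagged", undefined)
    return DistanceMatrix(aln.ids(), d, model)


@dataclass
class SpeciesSummary:
    """Per-species barcode-gap summary."""

    species: str
    n: int
    max_intra: float | None
    mean_intra: float | None
    se_intra: float | None
    nearest_species: str | None
    min_inter: float | None
    monophyletic: bool | None = None


def _species_members(
    m: DistanceMatrix,
    labels: Mapping[str, str | None],
    exclude_ids: set[str] | None,
) -> dict[str, list[int]]:
    exclude_ids = exclude_ids or set()
    members: dict[str, list[int]] = {}
    for seq_id in m.ids:
        if seq_id in exclude_ids:
            continue
        sp = labels.get(seq_id)
        if sp is None:
            continue
        members.setdefault(sp, []).append(m.index[seq_id])
    return members


def species_summaries(
    m: DistanceMatrix,
    labels: Mapping[str, str | None],
    exclude_ids: set[str] | None = None,
) -> list[SpeciesSummary]:
    """Per-species max/mean intraspecific distance and nearest neighbour.

    ``labels`` maps sequence id to binomial name (None = unidentified, the
    sequence is ignored).  ``exclude_ids`` removes flagged likely
    misidentifications before anything is computed.  Undefined distances
    are dropped from every min/max/mean.
    """
    members = _species_members(m, labels, exclude_ids)
    if not members:
        raise ValueError("no identified sequences to summarise")
    out: list[SpeciesSummary] = []
    for sp in sorted(members):
        idx = members[sp]
        max_intra = mean_intra = None
        if len(idx) >= 2:
            sub = m.d[np.ix_(idx, idx)]
            vals = sub[np.triu_indices(len(idx), k=1)]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                max_intra = float(vals.max())
                mean_intra = float(vals.mean())
        nearest, min_inter = None, None
        for other in sorted(members):
            if other == sp:
                continue
            cross = m.d[np.ix_(idx, members[other])].ravel()
            cross = cross[~np.isnan(cross)]
            if not len(cross):
                continue
            lo = float(cross.min())
            if min_inter is None or lo < min_inter:
                nearest, min_inter = other, lo
        out.append(
            SpeciesSummary(sp, len(idx), max_intra, mean_intra, None, nearest, min_inter)
        )
    return out


def low_interspecific_pairs(
    summaries: list[SpeciesSummary], cutoff: float = 0.03
) -> pd.DataFrame:
    """Species pairs whose minimum interspecific distance is below cutoff."""
    rows = []
    seen = set()
    for s in summaries:
        if s.min_inter is None or s.min_inter >= cutoff:
            continue
        key = tuple(sorted((s.species, s.nearest_species)))
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {"species_a": key[0], "species_b": key[1], "min_inter": s.min_inter}
        )
    return pd.DataFrame(rows, columns=["species_a", "species_b", "min_inter"]).sort_values(
        "min_inter", ignore_index=True
    )


def high_intraspecific_species(
    summaries: list[SpeciesSummary], cutoff: float = 0.02
) -> pd.DataFrame:
    """Species whose maximum intraspecific distance exceeds cutoff."""
    rows = [
        {
            "species": s.species,
            "n": s.n,
            "max_intra": s.max_intra,
            "mean_intra": s.mean_intra,
        }
        for s in summaries
        if s.max_intra is not None and s.max_intra > cutoff
    ]
    return pd.DataFrame(rows, columns=["species", "n", "max_intra", "mean_intra"]).sort_values(
        "max_intra", ascending=False, ignore_index=True
    )


def mean_intraspecific(aln: Alignment, labels: Mapping[str, str | None], model: str = "K2P") -> float:
    """Mean within-species distance pooled over all conspecific pairs."""
    m = distance_matrix(aln, model)
    members = _species_members(m, labels, None)
    vals: list[float] = []
    for idx in members.values():
        if len(idx) < 2:
            continue
        sub = m.d[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        vals.extend(sub[~np.isnan(sub)].tolist())
    if not vals:
        return math.nan
    return float(np.mean(vals))


def bootstrap_se(
    aln: Alignment,
    labels: Mapping[str, str | None],
    statistic: Callable[[Alignment, Mapping[str, str | None]], float],
    reps: int = 500,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of an alignment statistic.

    Alignment columns are resampled with replacement (MEGA-style), the
    statistic recomputed per replicate, and the SE is the standard deviation
    across replicates.  Replicates where the statistic is undefined (NaN)
    are dropped with a logged count.  Deterministic given the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    seqs = [list(r.seq) for r in aln]
    values: list[float] = []
    dropped = 0
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        recs = [
            replace(rec, seq="".join(seq[c] for c in cols))
            for rec, seq in zip(aln.records, seqs)
        ]
        v = statistic(Alignment(recs), labels)
        if math.isnan(v):
            dropped += 1
        else:
            values.append(v)
    if dropped:
        logger.warning("bootstrap: %d/%d replicates undefined, dropped", dropped, reps)
    if not values:
        return math.nan
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
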