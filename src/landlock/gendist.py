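"""Tamura–Nei (TN93) evolutionary distances, with optional gamma rate correction.

The TN93 model distinguishes the two transition classes (A<->G among purines,
C<->T among pyrimidines) from transversions and allows unequal base
frequencies.  Writing ``P1, P2, Q`` for the observed proportions of purine
transitions, pyrimidine transitions and transversions, and ``gA..gT`` for base
frequencies estimated from the two sequences pooled (``gR = gA+gG``,
``gY = gC+gT``), the distance is

    d = -k1 ln(w1) - k2 ln(w2) - k3 ln(w3)

    k1 = 2 gA gG / gR                    w1 = 1 - P1/k1 - Q/(2 gR)
    k2 = 2 gT gC / gY                    w2 = 1 - P2/k2 - Q/(2 gY)
    k3 = 2 (gR gY - gA gG gY/gR - gT gC gR/gY)
                                         w3 = 1 - Q/(2 gR gY)

Under gamma-distributed rate variation across sites with shape ``a`` the
logarithms are replaced by their continuous-gamma analogues,
``-ln(w) -> a (w^(-1/a) - 1)``, which converges to the plain TN93 distance as
``a -> infinity``.  A log argument ``w <= 0`` means the pair is saturated: the
distance is undefined and flagged rather than raised.

Group summaries (:func:`group_mean_distance`, :func:`within_group_diversity`)
are plain arithmetic means over the relevant pairs, excluding saturated pairs
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import SequenceTable, encode

# mismatch classification lookup over code pairs a*4+b
_PUR_TS = np.zeros(16, dtype=bool)
_PYR_TS = np.zeros(16, dtype=bool)
_TV = np.zeros(16, dtype=bool)
for _a in range(4):
    for _b in range(4):
        if _a == _b:
            continue
        pair = {_a, _b}
        if pair == {0, 2}:  # A,G
            _PUR_TS[_a * 4 + _b] = True
        elif pair == {1, 3}:  # C,T
            _PYR_TS[_a * 4 + _b] = True
        else:
            _TV[_a * 4 + _b] = True


class SaturationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class DistanceModelSpec:
    """Which distance to compute.

    model : ``"p-distance"``, ``"TN93"`` or ``"TN93+G"``.
    gamma_shape : gamma shape parameter ``a`` (used by ``TN93+G`` only).
    pooled_frequencies : estimate base frequencies per pair from the two
        sequences pooled (the usual pairwise convention); if False, use
        frequencies pooled over the whole table.
    """

    model: str = "TN93+G"
    gamma_shape: float = 0.14
    deletion: str = "complete"
    pooled_frequencies: bool = True

    def __post_init__(self):
        if self.model not in ("p-distance", "TN93", "TN93+G"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "TN93+G" and not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be > 0 for TN93+G")
        if self.deletion != "complete":
            raise ValueError("only complete deletion is supported")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with model metadata.

    Saturated pairs hold ``nan`` in ``values`` and True in ``saturated``.
    """

    labels: list[str]
    values: np.ndarray = field(repr=False)
    model: DistanceModelSpec
    saturated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if self.saturated is None:
            self.saturated = np.isnan(self.values)
        finite = self.values[~self.saturated]
        if finite.size and (finite < -1e-12).any():
            raise ValueError("negative distances")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("matrix not symmetric")

    def __getitem__(self, pair):
        a, b = pair
        i, j = self.labels.index(a), self.labels.index(b)
        return self.values[i, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="")

    def submatrix_mean(self, rows, cols) -> float:
        """Mean of values[rows, cols] ignoring saturated pairs (with warning)."""
        block = self.values[np.ix_(rows, cols)]
        if np.isnan(block).any():
            warnings.warn(
                "saturated pairs excluded from group mean", SaturationWarning
            )
        return float(np.nanmean(block))


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int, np.ndarray]:
    """Counts (n_sites, purine ts, pyrimidine ts, tv) and pooled base counts."""
    ok = (a < 4) & (b < 4)
    a, b = a[ok], b[ok]
    idx = a * 4 + b
    n = a.size
    p1 = int(_PUR_TS[idx].sum())
    p2 = int(_PYR_TS[idx].sum())
    q = int(_TV[idx].sum())
    freqs = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    return n, p1, p2, q, freqs


def tn93_from_proportions(
    P1: float,
    P2: float,
    Q: float,
    freqs: np.ndarray,
    spec: DistanceModelSpec,
) -> float:
    """TN93 distance from observed proportions and base frequencies.

    Returns ``nan`` (saturation) when a log argument is non-positive.
    """
    gA, gC, gG, gT = np.asarray(freqs, dtype=float) / np.sum(freqs)
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gT * gC / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
                - (gT * gC * gR / gY if gY > 0 else 0.0))
    w1 = 1.0 - (P1 / k1 if k1 > 0 else 0.0) - (Q / (2.0 * gR) if gR > 0 else 0.0)
    w2 = 1.0 - (P2 / k2 if k2 > 0 else 0.0) - (Q / (2.0 * gY) if gY > 0 else 0.0)
    w3 = 1.0 - (Q / (2.0 * gR * gY) if gR * gY > 0 else 0.0)
    if min(w1, w2, w3) <= 0.0:
        return float("nan")
    if spec.model == "TN93":
        terms = [-np.log(w1), -np.log(w2), -np.log(w3)]
    else:  # TN93+G, continuous gamma analogue of the logarithm
        a = spec.gamma_shape
        terms = [a * (w ** (-1.0 / a) - 1.0) for w in (w1, w2, w3)]
    d = k1 * terms[0] + k2 * terms[1] + k3 * terms[2]
    return float(max(d, 0.0))


def tn93_distance(seq_a: str, seq_b: str, spec: DistanceModelSpec | None = None) -> float:
    """Distance between two aligned sequences under ``spec``.

    Sites where either sequence is ambiguous/gapped are ignored for this pair.
    Base frequencies are estimated from the two sequences pooled.
    """
    spec = spec or DistanceModelSpec()
    a, b = encode(seq_a), encode(seq_b)
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    n, p1, p2, q, freqs = _pair_counts(a, b)
    if n == 0:
        raise ValueError("no comparable sites")
    if spec.model == "p-distance":
        return (p1 + p2 + q) / n
    return tn93_from_proportions(p1 / n, p2 / n, q / n, freqs, spec)


def pairwise_matrix(
    table: SequenceTable | list[str],
    spec: DistanceModelSpec | None = None,
    labels: list[str] | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix for a sequence table (or raw sequence list).

    Complete deletion is applied table-wide, then each unordered pair gets
    :func:`tn93_distance` semantics; with ``pooled_frequencies=False`` base
    frequencies come from the whole table instead of each pair.
    """
    spec = spec or DistanceModelSpec()
    if isinstance(table, SequenceTable):
        labels = labels or table.ids
        matrix = table.to_matrix()
    else:
        labels = labels or [str(i) for i in range(len(table))]
        matrix = np.stack([encode(s) for s in table])
    keep = (matrix < 4).all(axis=0)
    matrix = matrix[:, keep]
    n_ind, L = matrix.shape
    global_freqs = np.bincount(matrix.ravel(), minlength=4)[:4]
    out = np.zeros((n_ind, n_ind))
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            ns, p1, p2, q, freqs = _pair_counts(matrix[i], matrix[j])
            if spec.model == "p-distance":
                d = (p1 + p2 + q) / ns
            else:
                use = freqs if spec.pooled_frequencies else global_freqs
                d = tn93_from_proportions(p1 / ns, p2 / ns, q / ns, use, spec)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels=list(labels), values=out, model=spec)


def _group_indices(matrix: DistanceMatrix, group) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(matrix.labels)}
    try:
        return np.array([pos[g] for g in group], dtype=int)
    except KeyError as exc:
        raise KeyError(f"label {exc.args[0]!r} not in distance matrix") from exc


def group_mean_distance(matrix: DistanceMatrix, group_a, group_b) -> float:
    """Arithmetic mean distance over all inter-group pairs."""
    ia, ib = _group_indices(matrix, group_a), _group_indices(matrix, group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty group")
    if set(ia) & set(ib):
        raise ValueError("groups overlap")
    return matrix.submatrix_mean(ia, ib)


def within_group_diversity(matrix: DistanceMatrix, group) -> float:
    """Mean distance over all intra-group unordered pairs."""
    idx = _group_indices(matrix, group)
    if idx.size < 2:
        raise ValueError("diversity needs at least 2 members")
    block = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    vals = block[iu]
    if np.isnan(vals).any():
        warnings.warn("saturated pairs excluded from diversity", SaturationWarning)
    return float(np.nanmean(vals))
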