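"""Pairwise evolutionary distances and the full distance matrix.

The default model is F84 (unequal base frequencies, transition /
transversion distinction), used as a closed-form pairwise distance.
With transition proportion P, transversion proportion Q and base
frequencies pi, writing piR = piA + piG, piY = piC + piT and

    A = piC*piT/piY + piA*piG/piR
    B = piC*piT + piA*piG
    C = piR*piY

the F84 distance is

    d = -2*A*ln(1 - P/(2*A) - (A - B)*Q/(2*A*C)) + 2*(A - B - C)*ln(1 - Q/(2*C))

which reduces exactly to the Kimura two-parameter (K80) distance when
the base frequencies are uniform.  K80, JC69 and the raw proportion of
differing sites are provided as alternates.

Missing data policy: pairwise deletion.  A site enters a pair's counts
only when both sequences carry an unambiguous base (A, C, G or T);
gaps, ``?`` and IUPAC ambiguity codes are excluded for that pair only.
Base frequencies are estimated once from the whole alignment, so the
matrix stays consistent across taxon subsets.

Distances are substitutions per site (proportions).  Percent-scale
reporting (100x) belongs to the presentation layer.

Saturation (a logarithm argument <= 0) yields an *undefined* cell,
stored as NaN and flagged, never an exception here; consumers that
cannot tolerate undefined cells (tree building, taxon ordering) refuse
them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from homodist.alignment import Alignment

MODELS = ("F84", "K80", "JC69", "raw")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceError(ValueError):
    """Raised when a distance cannot be computed under the model contract."""


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion counts for one sequence pair.

    ``n_compared`` counts sites where both sequences carry an
    unambiguous base; P and Q are the transition and transversion
    proportions over those sites.
    """

    n_compared: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared


@dataclass(frozen=True)
class BaseFrequencies:
    """Relative A/C/G/T frequencies (each in (0,1), summing to 1)."""

    pi_A: float
    pi_C: float
    pi_G: float
    pi_T: float

    def __post_init__(self) -> None:
        freqs = (self.pi_A, self.pi_C, self.pi_G, self.pi_T)
        if any(not (0.0 < f < 1.0) for f in freqs):
            raise DistanceError(
                "degenerate base composition: every base frequency must be in "
                f"(0,1), got {freqs}; use a frequency-free model (K80/JC69/raw)"
            )
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise DistanceError(f"base frequencies must sum to 1, got {sum(freqs)}")

    @property
    def pi_R(self) -> float:
        return self.pi_A + self.pi_G

    @property
    def pi_Y(self) -> float:
        return self.pi_C + self.pi_T

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls(0.25, 0.25, 0.25, 0.25)

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_A, self.pi_C, self.pi_G, self.pi_T])


def encode_unambiguous(row: str) -> np.ndarray:
    """Encode a sequence as int8 codes: A=0, C=1, G=2, T=3, other=-1."""
    out = np.full(len(row), -1, dtype=np.int8)
    arr = np.frombuffer(row.encode("ascii"), dtype="S1")
    for base, code in _BASE_CODE.items():
        out[arr == base.encode()] = code
    return out


def _pair_counts_from_codes(ci: np.ndarray, cj: np.ndarray) -> PairCounts:
    both = (ci >= 0) & (cj >= 0)
    n_comp = int(both.sum())
    if n_comp == 0:
        raise DistanceError("no comparable sites between the two sequences")
    a, b = ci[both], cj[both]
    diff = a != b
    # purines are codes {0,2}, pyrimidines {1,3}: a difference is a
    # transition exactly when the two codes share parity.
    transitions = int((diff & ((a & 1) == (b & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return PairCounts(n_comp, transitions, transversions)


def count_pair_differences(row_i: str, row_j: str) -> PairCounts:
    """Count transitions/transversions between two equal-length rows.

    Pairwise deletion: sites where either row has a gap, ``?`` or an
    ambiguity code are excluded entirely.
    """
    if len(row_i) != len(row_j):
        raise DistanceError("sequences have unequal lengths")
    return _pair_counts_from_codes(encode_unambiguous(row_i), encode_unambiguous(row_j))


def estimate_base_frequencies(aln: Alignment) -> BaseFrequencies:
    """Estimate A/C/G/T frequencies over all rows and sites.

    Gaps and ambiguity codes are ignored.  A composition with any base
    absent is an error: the F84 closed form divides by frequency sums.
    """
    counts = np.zeros(4, dtype=np.int64)
    for row in aln.rows:
        codes = encode_unambiguous(row)
        counts += np.bincount(codes[codes >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise DistanceError("alignment contains no unambiguous bases")
    freqs = counts / total
    return BaseFrequencies(*freqs)


def f84_distance(pc: PairCounts, freqs: BaseFrequencies) -> float:
    """F84 distance for one pair; NaN when saturated (log argument <= 0)."""
    P, Q = pc.P, pc.Q
    A = freqs.pi_C * freqs.pi_T / freqs.pi_Y + freqs.pi_A * freqs.pi_G / freqs.pi_R
    B = freqs.pi_C * freqs.pi_T + freqs.pi_A * freqs.pi_G
    C = freqs.pi_R * freqs.pi_Y
    arg1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    arg2 = 1.0 - Q / (2.0 * C)
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan
    return -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)


def k80_distance(pc: PairCounts) -> float:
    """Kimura two-parameter distance; NaN when saturated."""
    P, Q = pc.P, pc.Q
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def jc69_distance(pc: PairCounts) -> float:
    """Jukes-Cantor distance; NaN when saturated."""
    p = pc.P + pc.Q
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def raw_distance(pc: PairCounts) -> float:
    """Uncorrected proportion of differing sites (p-distance)."""
    return pc.P + pc.Q


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels.

    Undefined (saturated) cells are NaN; ``undefined_pairs`` lists them.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    undefined_pairs: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise DistanceError("matrix shape does not match label count")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise DistanceError("diagonal must be zero")
        mask = ~np.isnan(v)
        if not np.array_equal(mask, mask.T) or not np.allclose(
            v[mask & mask.T], v.T[mask & mask.T]
        ):
            raise DistanceError("matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(v[mask] < 0):
                raise DistanceError("negative distance")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon label: {label!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset(self, labels: Iterable[str]) -> "DistanceMatrix":
        """Slice to ``labels``, keeping the given order."""
        labels = tuple(labels)
        idx = [self.index(lab) for lab in labels]
        sub = self.values[np.ix_(idx, idx)]
        undef = tuple(
            (a, b)
            for a, b in self.undefined_pairs
            if a in labels and b in labels
        )
        return DistanceMatrix(labels, sub, undef)

    def max_distance(self) -> float:
        """Largest defined off-diagonal distance (MaxD of this taxon set)."""
        if self.n < 2:
            return 0.0
        off = self.values[~np.eye(self.n, dtype=bool)]
        return float(np.nanmax(off))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.10g")

    def write_phylip(self, path: Union[str, Path]) -> None:
        """Square PHYLIP matrix (labels padded to >= 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.values):
                cells = " ".join(f"{x:.6f}" for x in row)
                fh.write(f"{lab:<10s} {cells}\n")


_PAIR_MODEL = {
    "K80": k80_distance,
    "JC69": jc69_distance,
    "raw": raw_distance,
}


def distance_matrix(aln: Alignment, model: str = "F84") -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` (F84, K80, JC69 or raw).

    F84 uses base frequencies estimated once from the whole alignment.
    A pair with zero comparable sites is an error naming the pair;
    saturation is recorded as an undefined (NaN) cell.
    """
    if model not in MODELS:
        raise DistanceError(f"unknown model {model!r}; choose from {MODELS}")
    if aln.n_taxa < 2:
        raise DistanceError("need at least 2 taxa")
    if model == "F84":
        freqs = estimate_base_frequencies(aln)
        pair_fn = lambda pc: f84_distance(pc, freqs)  # noqa: E731
    else:
        pair_fn = _PAIR_MODEL[model]
    codes = [encode_unambiguous(row) for row in aln.rows]
    n = aln.n_taxa
    values = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pc = _pair_counts_from_codes(codes[i], codes[j])
            except DistanceError:
                raise DistanceError(
                    "no comparable sites between "
                    f"{aln.labels[i]!r} and {aln.labels[j]!r}"
                ) from None
            d = pair_fn(pc)
            values[i, j] = values[j, i] = d
            if math.isnan(d):
                undefined.append((aln.labels[i], aln.labels[j]))
    return DistanceMatrix(aln.labels, values, tuple(undefined))
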