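"""The incremental taxon-addition trace engine and its downstream analyses.

Procedure: compute the full pairwise distance matrix once; pick the
center of the distribution (the taxon with the lowest average distance
to all others) or accept an operator-chosen one; order the remaining
taxa by increasing distance from the center; build the first tree from
the center plus its three closest taxa, then add one taxon per step,
rebuilding the tree(s) on the growing subset and recomputing the
parsimony homoplasy indices on the sub-alignment at every step.

Per step the trace records, for each configured tree method (NJ and/or
UPGMA):

* ``disCen`` — distance of the newly added taxon from the center
  (step 1 records the third-closest taxon's distance);
* ``MaxD``  — maximum pairwise distance within the current subset;
* S, M, G, CI, RI (or NA), HI = 1 - CI, RCI (or NA);
* SHI = HI / MaxD (0 when MaxD = 0), the distance-normalised
  homoplasy index.

Downstream analyses: the Pearson correlation between MaxD and CI over
steps with CI < 1; the earliest step at which HI becomes positive; and
partitioning of the taxon series at HI change points, reported as
auxiliary species-delimitation evidence (never as automatic species
decisions).

The whole pipeline is deterministic given input order: ties in center
choice and ordering fall back to input order, and tree construction
uses documented index tie-breaks.  No random number source is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from homodist.alignment import Alignment, trim_flanking_columns
from homodist.distances import DistanceMatrix, distance_matrix, MODELS
from homodist.parsimony import consistency_indices
from homodist.trees import build_nj, build_upgma, to_newick

TREE_METHODS = ("nj", "upgma")

_BUILDERS = {"nj": build_nj, "upgma": build_upgma}


class HomoDistError(ValueError):
    """Raised on invalid run configurations or inputs."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a trace run.

    ``auto_center`` mirrors the classic autCen switch: when true the
    center is searched automatically; when false ``center`` must name a
    taxon label or give its 1-based position in the alignment (defCen).
    ``model`` is the distance model (distmodel; default F84).
    """

    auto_center: bool = True
    center: Union[str, int, None] = None
    model: str = "F84"
    methods: tuple[str, ...] = ("nj", "upgma")
    trim: bool = False
    hi_decimals: int = 4

    def __post_init__(self) -> None:
        if not self.auto_center and self.center is None:
            raise HomoDistError("center (defCen) required when auto_center is off")
        if self.model not in MODELS:
            raise HomoDistError(f"unsupported model {self.model!r}; choose from {MODELS}")
        bad = set(self.methods) - set(TREE_METHODS)
        if bad or not self.methods:
            raise HomoDistError(f"tree methods must be a non-empty subset of {TREE_METHODS}")

    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        """Read a key=value config file using the classic argument names
        (autCen, defCen, distmodel) alongside this class's field names."""
        rename = {"autcen": "auto_center", "defcen": "center", "distmodel": "model"}
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise HomoDistError(f"bad config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            key = rename.get(key.lower(), key.lower())
            if key in ("auto_center", "trim"):
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif key == "hi_decimals":
                kwargs[key] = int(value)
            elif key == "methods":
                kwargs[key] = tuple(m.strip().lower() for m in value.split(","))
            elif key == "center":
                kwargs[key] = int(value) if value.isdigit() else value
            elif key == "model":
                kwargs[key] = value
            else:
                raise HomoDistError(f"unknown config key {key!r}")
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class MethodScores:
    """Per-tree-method metrics of one trace step."""

    S: int
    M: int
    G: int
    ci: float
    ri: Optional[float]
    hi: float
    rci: Optional[float]
    shi: float
    newick: Optional[str] = None


@dataclass(frozen=True)
class TraceStep:
    """One taxon addition: the subset, its span, and per-method scores."""

    step_index: int
    added_taxon: str
    taxa: tuple[str, ...]
    dis_cen: float
    max_d: float
    scores: dict[str, MethodScores]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class HomoDistTrace:
    """The full ordered trace of a run."""

    center: str
    series: tuple[str, ...]
    steps: tuple[TraceStep, ...]
    config: RunConfig

    @property
    def methods(self) -> tuple[str, ...]:
        return self.config.methods

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for st in self.steps:
            row: dict = {
                "step": st.step_index,
                "added_taxon": st.added_taxon,
                "n_taxa": st.n_taxa,
                "disCen": st.dis_cen,
                "MaxD": st.max_d,
            }
            for m in self.methods:
                sc = st.scores[m]
                row[f"{m}_S"] = sc.S
                row[f"{m}_M"] = sc.M
                row[f"{m}_G"] = sc.G
                row[f"{m}_CI"] = sc.ci
                row[f"{m}_RI"] = sc.ri
                row[f"{m}_HI"] = sc.hi
                row[f"{m}_RCI"] = sc.rci
                row[f"{m}_SHI"] = sc.shi
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: Union[str, Path]) -> None:
        """One row per step; unavailable RI/RCI spelled ``NA``.

        The center and the full ordered series go into ``#`` comment
        lines so the file round-trips without losing the three taxa
        that enter silently with step 1.
        """
        with open(path, "w") as fh:
            fh.write(f"# center: {self.center}\n")
            fh.write(f"# series: {','.join(self.series)}\n")
            self.to_dataframe().to_csv(
                fh, sep="\t", index=False, na_rep="NA", float_format="%.10g"
            )


@dataclass(frozen=True)
class GroupPartition:
    """Taxa partitioned at HI change points along the series.

    ``groups`` is an ordered list of (labels, HI) pairs; ``boundaries``
    lists the step indices at which HI changed.
    """

    groups: tuple[tuple[tuple[str, ...], float], ...]
    boundaries: tuple[int, ...] = field(default=())

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def labels(self) -> tuple[str, ...]:
        return tuple(lab for grp, _ in self.groups for lab in grp)


def find_center(D: DistanceMatrix) -> str:
    """Taxon with the lowest average distance to all others.

    Ties resolve to the earliest label in input order.  Undefined cells
    are refused: an average over a saturated distance is meaningless.
    """
    if D.has_undefined:
        pairs = ", ".join(f"{a}/{b}" for a, b in D.undefined_pairs)
        raise HomoDistError(f"cannot find center with undefined distances: {pairs}")
    means = D.values.sum(axis=1) / (D.n - 1)
    return D.labels[int(np.argmin(means))]


def order_by_center_distance(D: DistanceMatrix, center: str) -> tuple[str, ...]:
    """Center first, then the rest by increasing distance from it.

    The sort is stable: taxa at equal distance keep their input order.
    """
    ci = D.index(center)
    row = D.values[ci]
    if np.isnan(row).any():
        bad = [D.labels[k] for k in np.nonzero(np.isnan(row))[0]]
        raise HomoDistError(
            f"distance from center {center!r} undefined for: {', '.join(bad)}"
        )
    others = [k for k in range(D.n) if k != ci]
    others.sort(key=lambda k: row[k])  # stable: ties keep input order
    return (center,) + tuple(D.labels[k] for k in others)


def _resolve_center(cfg: RunConfig, aln: Alignment, D: DistanceMatrix) -> str:
    if cfg.auto_center:
        return find_center(D)
    if isinstance(cfg.center, int):
        if not 1 <= cfg.center <= aln.n_taxa:
            raise HomoDistError(
                f"center position {cfg.center} out of range 1..{aln.n_taxa}"
            )
        return aln.labels[cfg.center - 1]
    if cfg.center not in aln.labels:
        raise HomoDistError(f"center label {cfg.center!r} not in alignment")
    return cfg.center


def run_homodist(
    aln: Alignment,
    cfg: RunConfig = RunConfig(),
    keep_trees: bool = True,
) -> HomoDistTrace:
    """Run the full trace on an alignment.

    The distance matrix is computed once on the whole alignment and
    sliced per step (pairwise-deletion distances do not depend on which
    other taxa are present).  Step 1 scores the center plus its three
    closest taxa; each later step adds the next taxon in the series.
    """
    if cfg.trim:
        aln = trim_flanking_columns(aln)
    if aln.n_taxa < 4:
        raise HomoDistError(f"need >= 4 taxa for the first tree, got {aln.n_taxa}")
    D = distance_matrix(aln, cfg.model)
    center = _resolve_center(cfg, aln, D)
    series = order_by_center_distance(D, center)
    steps = []
    for k in range(4, len(series) + 1):
        taxa = series[:k]
        added = series[k - 1]
        sub_d = D.subset(taxa)
        if sub_d.has_undefined:
            pairs = ", ".join(f"{a}/{b}" for a, b in sub_d.undefined_pairs)
            raise HomoDistError(f"saturated distance within step {k - 3} subset: {pairs}")
        sub_aln = aln.subset(taxa)
        dis_cen = D.get(center, added)
        max_d = sub_d.max_distance()
        scores: dict[str, MethodScores] = {}
        for method in cfg.methods:
            tree = _BUILDERS[method](sub_d)
            ps = consistency_indices(tree, sub_aln)
            shi = 0.0 if max_d == 0 else ps.hi / max_d
            scores[method] = MethodScores(
                S=ps.S, M=ps.M, G=ps.G,
                ci=ps.ci, ri=ps.ri, hi=ps.hi, rci=ps.rci, shi=shi,
                newick=to_newick(tree) if keep_trees else None,
            )
        steps.append(
            TraceStep(
                step_index=k - 3,
                added_taxon=added,
                taxa=taxa,
                dis_cen=dis_cen,
                max_d=max_d,
                scores=scores,
            )
        )
    return HomoDistTrace(center=center, series=series, steps=tuple(steps), config=cfg)


def _check_method(trace: HomoDistTrace, method: str) -> str:
    method = method.lower()
    if method not in trace.methods:
        raise HomoDistError(
            f"method {method!r} not in this trace (has {trace.methods})"
        )
    return method


def first_homoplasy_step(trace: HomoDistTrace, method: str = "nj") -> Optional[TraceStep]:
    """Earliest step with HI > 0 for ``method``; None when HI stays 0.

    The step carries both candidate 'detection distances': the added
    taxon's distance from the center (``dis_cen``) and the subset span
    (``max_d``).
    """
    method = _check_method(trace, method)
    for st in trace.steps:
        if st.scores[method].hi > 0.0:
            return st
    return None


def ci_distance_correlation(trace: HomoDistTrace, method: str = "nj") -> Optional[float]:
    """Pearson correlation between MaxD and CI over steps with CI < 1.

    Only steps showing some homoplasy (CI < 1) qualify.  Returns None
    with fewer than 3 qualifying steps or zero variance in either
    variable.
    """
    method = _check_method(trace, method)
    xs, ys = [], []
    for st in trace.steps:
        ci = st.scores[method].ci
        if ci < 1.0:
            xs.append(st.max_d)
            ys.append(ci)
    if len(xs) < 3:
        return None
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:  # zero variance in either variable
        return None
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def delimit_hi_groups(
    trace: HomoDistTrace,
    method: str = "nj",
    decimals: Optional[int] = None,
) -> GroupPartition:
    """Partition the taxon series wherever HI changes between steps.

    The center and the three taxa of step 1 share step 1's HI; every
    later taxon carries the HI of the step that added it.  A new group
    opens when HI (rounded to ``decimals`` places, default from the run
    config) differs from the previous step's.  HI typically changes at
    the transition between species, so groups are auxiliary
    delimitation evidence.
    """
    method = _check_method(trace, method)
    if decimals is None:
        decimals = trace.config.hi_decimals
    groups: list[tuple[tuple[str, ...], float]] = []
    boundaries: list[int] = []
    current: list[str] = []
    current_hi: Optional[float] = None
    for st in trace.steps:
        hi = round(st.scores[method].hi, decimals)
        members = list(st.taxa) if st.step_index == 1 else [st.added_taxon]
        if current_hi is None or hi == current_hi:
            current.extend(members)
        else:
            groups.append((tuple(current), current_hi))
            boundaries.append(st.step_index)
            current = list(members)
        current_hi = hi
    groups.append((tuple(current), current_hi if current_hi is not None else 0.0))
    return GroupPartition(groups=tuple(groups), boundaries=tuple(boundaries))


def trace_from_tsv(path: Union[str, Path]) -> HomoDistTrace:
    """Rebuild a trace from its TSV export (tree files not restored).

    Good enough for the downstream analyses, which only need the metric
    columns; the taxon subsets are reconstructed from the series order.
    """
    header_series: Optional[list[str]] = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# series:"):
                header_series = line.split(":", 1)[1].strip().split(",")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")
    methods = tuple(m for m in TREE_METHODS if f"{m}_CI" in df.columns)
    if not methods:
        raise HomoDistError(f"no per-method metric columns found in {path}")
    if df.empty:
        raise HomoDistError(f"empty trace file {path}")
    first = df.iloc[0]
    n0 = int(first["n_taxa"])
    if n0 != 4:
        raise HomoDistError("trace must start with a 4-taxon step")
    # the three taxa entering silently with step 1 come from the series
    # comment line; placeholders keep older files readable.
    if header_series is not None:
        series: list[str] = list(header_series[:3])
    else:
        series = [f"<center+{i}>" for i in range(3)]
    steps = []
    for _, row in df.iterrows():
        series.append(str(row["added_taxon"]))
        scores = {}
        for m in methods:
            ri = row[f"{m}_RI"]
            rci = row[f"{m}_RCI"]
            scores[m] = MethodScores(
                S=int(row[f"{m}_S"]), M=int(row[f"{m}_M"]), G=int(row[f"{m}_G"]),
                ci=float(row[f"{m}_CI"]),
                ri=None if pd.isna(ri) else float(ri),
                hi=float(row[f"{m}_HI"]),
                rci=None if pd.isna(rci) else float(rci),
                shi=float(row[f"{m}_SHI"]),
            )
        steps.append(
            TraceStep(
                step_index=int(row["step"]),
                added_taxon=str(row["added_taxon"]),
                taxa=tuple(series),
                dis_cen=float(row["disCen"]),
                max_d=float(row["MaxD"]),
                scores=scores,
            )
        )
    cfg = RunConfig(methods=methods)
    center = series[0] if steps else "<center>"
    return HomoDistTrace(center=center, series=tuple(series), steps=tuple(steps), config=cfg)
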