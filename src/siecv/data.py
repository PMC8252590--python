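"""Clustered individual-participant data, model terms, and design matrices.

The central container is :class:`ClusteredDataset`: one row per participant,
a categorical cluster label (study, centre, region, ...), a binary outcome
and numeric predictor columns.  Model structure is expressed as a list of
:class:`Term` objects; :func:`build_design` turns a dataset plus a
:class:`ModelSpec` into a numeric design matrix with an explicit intercept
column.

Transforms supported on a term are deliberately few: identity, scaling by a
constant (e.g. age/25, so that coefficients are reported on a convenient
scale), natural log, and square-after-within-cluster-centering (so that a
positive quadratic coefficient means risk rises for values away from the
cluster mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError

INTERCEPT = "(Intercept)"

_TRANSFORM_KINDS = ("identity", "scale", "log", "square_centered")
_TERM_KINDS = ("main", "transform", "interaction")


@dataclass(frozen=True)
class Transform:
    """A deterministic column transform.

    kind:
        "identity", "scale" (multiply by ``constant``), "log" (natural log),
        or "square_centered" (multiply by ``constant``, subtract the
        within-cluster mean, square).
    constant:
        multiplier applied before any centering; 1.0 for identity/log.
    """

    kind: str = "identity"
    constant: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _TRANSFORM_KINDS:
            raise ConfigurationError(f"unknown transform kind {self.kind!r}")

    @property
    def is_centered(self) -> bool:
        return self.kind == "square_centered"


@dataclass(frozen=True)
class Term:
    """One model term: a main effect, a transformed variable, or an interaction.

    ``sources`` are base column names in the dataset.  An interaction takes
    the elementwise product of its (transformed) sources; ``transforms`` is
    then parallel to ``sources``.  A main/transform term has exactly one
    source.
    """

    name: str
    kind: str = "main"
    sources: tuple[str, ...] = ()
    transforms: tuple[Transform, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _TERM_KINDS:
            raise ConfigurationError(f"unknown term kind {self.kind!r}")
        sources = tuple(self.sources) or (self.name,)
        object.__setattr__(self, "sources", sources)
        transforms = tuple(self.transforms)
        if not transforms:
            transforms = tuple(Transform() for _ in sources)
        if len(transforms) != len(sources):
            raise ConfigurationError(
                f"term {self.name!r}: {len(sources)} sources but "
                f"{len(transforms)} transforms"
            )
        object.__setattr__(self, "transforms", transforms)
        if self.kind == "interaction" and len(sources) < 2:
            raise ConfigurationError(
                f"interaction term {self.name!r} needs >= 2 sources"
            )
        if self.kind in ("main", "transform") and len(sources) != 1:
            raise ConfigurationError(
                f"{self.kind} term {self.name!r} must have exactly 1 source"
            )

    @property
    def is_centered(self) -> bool:
        return any(t.is_centered for t in self.transforms)


def main_term(name: str) -> Term:
    return Term(name=name, kind="main", sources=(name,))


def scaled_term(name: str, source: str, constant: float) -> Term:
    return Term(
        name=name, kind="transform", sources=(source,),
        transforms=(Transform("scale", constant),),
    )


def log_term(name: str, source: str) -> Term:
    return Term(name=name, kind="transform", sources=(source,),
                transforms=(Transform("log"),))


def squared_term(name: str, source: str, constant: float = 1.0) -> Term:
    """Square of a (scaled) variable after within-cluster centering."""
    return Term(
        name=name, kind="transform", sources=(source,),
        transforms=(Transform("square_centered", constant),),
    )


def interaction_term(name: str, sources: Sequence[str],
                     transforms: Sequence[Transform] | None = None) -> Term:
    return Term(name=name, kind="interaction", sources=tuple(sources),
                transforms=tuple(transforms or ()))


@dataclass
class ClusteredDataset:
    """Participant-level data with a cluster label and binary outcome.

    Cluster order is the order of first appearance in the source table and
    is preserved by every iteration in the package, so that repeated runs
    visit clusters identically.
    """

    frame: pd.DataFrame
    cluster_col: str
    outcome_col: str

    def __post_init__(self) -> None:
        self._validate()
        labels = self.frame[self.cluster_col]
        # first-appearance order, stable across runs
        self.cluster_labels: list = list(dict.fromkeys(labels))

    def _validate(self) -> None:
        for col in (self.cluster_col, self.outcome_col):
            if col not in self.frame.columns:
                raise ConfigurationError(f"column {col!r} not found in data")
        if self.frame.isna().any().any():
            bad = [c for c in self.frame.columns if self.frame[c].isna().any()]
            raise DataValidationError(
                f"missing values in column(s) {bad}; impute upstream"
            )
        y = self.frame[self.outcome_col]
        if not set(np.unique(y)) <= {0, 1}:
            raise DataValidationError(
                f"outcome {self.outcome_col!r} must be coded 0/1, "
                f"found values {sorted(set(np.unique(y)))[:6]}"
            )
        if self.frame[self.cluster_col].nunique() < 2:
            raise DataValidationError("need at least 2 clusters")

    @property
    def K(self) -> int:
        return len(self.cluster_labels)

    @property
    def N(self) -> int:
        return len(self.frame)

    @property
    def predictor_columns(self) -> list[str]:
        return [c for c in self.frame.columns
                if c not in (self.cluster_col, self.outcome_col)]

    @property
    def n_k(self) -> dict:
        counts = self.frame[self.cluster_col].value_counts()
        return {k: int(counts[k]) for k in self.cluster_labels}

    def outcome(self, cluster=None) -> np.ndarray:
        frame = self.frame if cluster is None else self.cluster_rows(cluster)
        return frame[self.outcome_col].to_numpy(dtype=float)

    def cluster_rows(self, label) -> pd.DataFrame:
        return self.frame[self.frame[self.cluster_col] == label]

    def drop_cluster(self, label) -> "ClusteredDataset":
        kept = self.frame[self.frame[self.cluster_col] != label]
        return ClusteredDataset(kept.reset_index(drop=True),
                                self.cluster_col, self.outcome_col)

    def only_clusters(self, labels: Iterable) -> "ClusteredDataset":
        labels = set(labels)
        kept = self.frame[self.frame[self.cluster_col].isin(labels)]
        return ClusteredDataset(kept.reset_index(drop=True),
                                self.cluster_col, self.outcome_col)

    def events(self, cluster=None) -> int:
        return int(self.outcome(cluster).sum())

    def fit_viable(self, label) -> bool:
        """A cluster can be used for model fitting iff it has at least one
        event and one non-event."""
        y = self.outcome(label)
        return 0 < y.sum() < len(y)

    def to_csv(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def load_dataset(path, cluster_col: str, outcome_col: str,
                 sep: str = ",") -> ClusteredDataset:
    """Read a delimited text file into a validated ClusteredDataset."""
    frame = pd.read_csv(path, sep=sep)
    return ClusteredDataset(frame, cluster_col, outcome_col)


@dataclass
class ModelSpec:
    """The current model: included terms, forced terms, remaining candidates.

    The intercept is implicit and always present.  ``forced`` holds names of
    included terms that selection may never remove.  ``candidates`` is the
    ordered candidate set for the current cycle; order defines deterministic
    tie-breaking.
    """

    included: list[Term] = field(default_factory=list)
    forced: set[str] = field(default_factory=set)
    candidates: list[Term] = field(default_factory=list)
    cycle: int = 0

    def __post_init__(self) -> None:
        names = [t.name for t in self.included]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate term names in included set")
        overlap = set(names) & {t.name for t in self.candidates}
        if overlap:
            raise ConfigurationError(
                f"terms both included and candidate: {sorted(overlap)}"
            )
        missing = self.forced - set(names)
        if missing:
            raise ConfigurationError(
                f"forced terms not in included set: {sorted(missing)}"
            )

    @property
    def term_names(self) -> list[str]:
        return [INTERCEPT] + [t.name for t in self.included]

    def with_candidate(self, term: Term) -> "ModelSpec":
        """Move ``term`` from the candidate set into the model."""
        rest = [t for t in self.candidates if t.name != term.name]
        return ModelSpec(self.included + [term], set(self.forced), rest,
                         self.cycle + 1)

    def without_term(self, name: str) -> "ModelSpec":
        if name in self.forced:
            raise ConfigurationError(f"term {name!r} is forced; cannot remove")
        kept = [t for t in self.included if t.name != name]
        if len(kept) == len(self.included):
            raise ConfigurationError(f"term {name!r} not in model")
        return ModelSpec(kept, set(self.forced), list(self.candidates),
                         self.cycle + 1)

    def force(self, names: Iterable[str]) -> "ModelSpec":
        return ModelSpec(list(self.included),
                         set(self.forced) | set(names),
                         list(self.candidates), self.cycle)


def _transform_column(frame: pd.DataFrame, source: str, tr: Transform,
                      cluster_col: str,
                      center_means: Mapping | None) -> np.ndarray:
    x = frame[source].to_numpy(dtype=float)
    if tr.kind == "identity":
        return x
    if tr.kind == "scale":
        return x * tr.constant
    if tr.kind == "log":
        if np.any(x <= 0):
            raise DataValidationError(
                f"log transform on non-positive values in column {source!r}"
            )
        return np.log(x)
    # square_centered: scale, centre within cluster, square
    x = x * tr.constant
    if center_means is not None and source in center_means:
        mean_map = center_means[source]
        means = frame[cluster_col].map(mean_map).to_numpy(dtype=float) \
            if isinstance(mean_map, Mapping) else float(mean_map)
    else:
        means = (
            pd.Series(x, index=frame.index)
            .groupby(frame[cluster_col], sort=False)
            .transform("mean")
            .to_numpy()
        )
    return (x - means) ** 2


def build_design(data: ClusteredDataset, spec: ModelSpec,
                 center_means: Mapping | None = None) -> pd.DataFrame:
    """Build the design matrix: intercept column plus one column per term.

    ``center_means`` optionally overrides the within-cluster centering
    statistics for square-after-centering terms, keyed by source column name
    (value: scalar or cluster-label -> mean mapping, on the *scaled* axis).
    By default centering uses the means of the data the design is built on,
    so hold-out clusters are centered with their own means — what a deployed
    model would do, since development-cluster means are unavailable for a
    genuinely new cluster.
    """
    frame = data.frame
    cols: dict[str, np.ndarray] = {INTERCEPT: np.ones(len(frame))}
    for term in spec.included:
        for src in term.sources:
            if src not in frame.columns:
                raise ConfigurationError(
                    f"term {term.name!r} references missing column {src!r}"
                )
        parts = [
            _transform_column(frame, src, tr, data.cluster_col, center_means)
            for src, tr in zip(term.sources, term.transforms)
        ]
        col = parts[0]
        for extra in parts[1:]:
            col = col * extra
        cols[term.name] = col
    return pd.DataFrame(cols, index=frame.index)


def cluster_center_means(data: ClusteredDataset, spec: ModelSpec) -> dict:
    """Per-cluster means (on the scaled axis) for every centered source in
    ``spec``; used to carry development-data centering to hold-out rows."""
    out: dict[str, dict] = {}
    for term in spec.included:
        for src, tr in zip(term.sources, term.transforms):
            if tr.is_centered:
                x = data.frame[src].astype(float) * tr.constant
                out[src] = x.groupby(
                    data.frame[data.cluster_col], sort=False).mean().to_dict()
    return out


# --- serialization of term lists (YAML/JSON config blocks) -----------------

def term_to_dict(term: Term) -> dict:
    return {
        "name": term.name,
        "kind": term.kind,
        "sources": list(term.sources),
        "transforms": [
            {"kind": t.kind, "constant": t.constant} for t in term.transforms
        ],
    }


def term_from_dict(d: Mapping) -> Term:
    unknown = set(d) - {"name", "kind", "sources", "transforms", "transform"}
    if unknown:
        raise ConfigurationError(f"unknown term keys: {sorted(unknown)}")
    if "name" not in d:
        raise ConfigurationError("term descriptor missing 'name'")
    transforms = d.get("transforms")
    if transforms is None and "transform" in d:
        transforms = [d["transform"]]
    trs = tuple(
        Transform(t.get("kind", "identity"), float(t.get("constant", 1.0)))
        for t in (transforms or [])
    )
    return Term(
        name=d["name"],
        kind=d.get("kind", "main"),
        sources=tuple(d.get("sources", ())),
        transforms=trs,
    )
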