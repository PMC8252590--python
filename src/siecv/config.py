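"""Run-configuration parsing and validation (YAML/JSON).

A run config names the cluster and outcome columns, the candidate and
forced terms, the selection direction, the aggregated loss and its lambda,
and the meta-analysis estimator.  Unknown keys are rejected; defaults are
filled in and echoed so a report always shows the configuration actually
used.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .data import ModelSpec, Term, term_from_dict, term_to_dict
from .errors import ConfigurationError
from .losses import LOSS_FAMILIES
from .meta import METHODS

DEFAULTS = {
    "direction": "forward",
    "loss": "re",
    "lambda": 0.5,
    "tau_estimator": "REML",
    "require_main_effects": False,
    "c_stat_transform": "identity",
    "alpha": 0.05,
    "min_improvement": 0.0,
    "centering": "within",
    "delimiter": ",",
    "forced_terms": [],
    "base_terms": [],
}

_KNOWN = set(DEFAULTS) | {"cluster_col", "outcome_col", "terms"}


@dataclass
class RunConfig:
    cluster_col: str
    outcome_col: str
    candidates: list[Term]
    base_terms: list[Term] = field(default_factory=list)
    forced_terms: list[str] = field(default_factory=list)
    direction: str = "forward"
    loss: str = "re"
    lam: float = 0.5
    tau_estimator: str = "REML"
    require_main_effects: bool = False
    c_stat_transform: str = "identity"
    alpha: float = 0.05
    min_improvement: float = 0.0
    centering: str = "within"
    delimiter: str = ","

    def model_spec(self) -> ModelSpec:
        """Base ModelSpec for the configured run.

        Forward runs start from the base/forced terms with all configured
        terms as candidates; backward runs start from the full model.
        """
        if self.direction == "backward":
            included = self.base_terms + self.candidates
            return ModelSpec(included, set(self.forced_terms), [])
        return ModelSpec(list(self.base_terms), set(self.forced_terms),
                         list(self.candidates))

    def echo(self) -> dict:
        d = asdict(self)
        d["candidates"] = [term_to_dict(t) for t in self.candidates]
        d["base_terms"] = [term_to_dict(t) for t in self.base_terms]
        return d


def validate_config(raw: dict) -> RunConfig:
    """Type-check a parsed config dict; collect every problem, then raise."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _KNOWN
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULTS, **{k: v for k, v in raw.items() if k in _KNOWN}}

    for key in ("cluster_col", "outcome_col"):
        if key not in raw:
            errors.append(f"missing required key {key!r}")
    if "terms" not in raw or not raw["terms"]:
        errors.append("missing required key 'terms' (candidate term list)")

    lam = merged["lambda"]
    if not isinstance(lam, (int, float)) or not 0 <= lam <= 1:
        errors.append(f"lambda must be in [0, 1], got {lam!r}")
    if merged["loss"] not in LOSS_FAMILIES:
        errors.append(f"loss must be one of {LOSS_FAMILIES}, "
                      f"got {merged['loss']!r}")
    if merged["tau_estimator"] not in METHODS:
        errors.append(f"tau_estimator must be one of {METHODS}, "
                      f"got {merged['tau_estimator']!r}")
    if merged["direction"] not in ("forward", "backward"):
        errors.append(f"direction must be forward|backward, "
                      f"got {merged['direction']!r}")
    if merged["c_stat_transform"] not in ("identity", "logit"):
        errors.append("c_stat_transform must be identity|logit")
    if merged["centering"] not in ("within", "development"):
        errors.append("centering must be within|development")
    alpha = merged["alpha"]
    if not isinstance(alpha, (int, float)) or not 0 < alpha < 1:
        errors.append(f"alpha must be in (0, 1), got {alpha!r}")
    if not isinstance(merged["require_main_effects"], bool):
        errors.append("require_main_effects must be boolean")

    candidates: list[Term] = []
    base_terms: list[Term] = []
    try:
        candidates = [term_from_dict(d) for d in raw.get("terms", [])]
        base_terms = [term_from_dict(d) for d in merged["base_terms"]]
    except ConfigurationError as exc:
        errors.append(str(exc))

    forced = list(merged["forced_terms"])
    known_names = {t.name for t in base_terms}
    bad_forced = [f for f in forced if f not in known_names]
    if bad_forced:
        errors.append(
            f"forced_terms not among base_terms: {bad_forced} "
            "(forced terms must be present from cycle 0)"
        )

    if errors:
        raise ConfigurationError("; ".join(errors))

    return RunConfig(
        cluster_col=raw["cluster_col"], outcome_col=raw["outcome_col"],
        candidates=candidates, base_terms=base_terms, forced_terms=forced,
        direction=merged["direction"], loss=merged["loss"], lam=float(lam),
        tau_estimator=merged["tau_estimator"],
        require_main_effects=merged["require_main_effects"],
        c_stat_transform=merged["c_stat_transform"], alpha=float(alpha),
        min_improvement=float(merged["min_improvement"]),
        centering=merged["centering"], delimiter=merged["delimiter"],
    )


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config: {exc}") from exc
    return validate_config(raw or {})
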