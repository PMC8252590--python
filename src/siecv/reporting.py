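"""Structured outputs: trace JSON, forest tables, and run reports.

Everything rendered here is read from stored result objects — nothing is
recomputed at render time — and serialization is deterministic (sorted
keys, repr-based floats), so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json

import numpy as np

from .engine import GlobalModel, IECVResult, SIECVTrace
from .meta import PooledEstimate, PredictionInterval, forest_rows

FOREST_COLUMNS = ("label", "estimate", "lower", "upper", "weight_pct",
                  "is_summary", "is_pi")


def _clean(obj):
    """JSON-ready copy: numpy scalars to python, NaN to None, sorted keys."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def dumps(payload: dict) -> str:
    return json.dumps(_clean(payload), indent=2, sort_keys=True)


def pooled_to_dict(p: PooledEstimate,
                   pi: PredictionInterval | None = None) -> dict:
    d = {
        "value": p.value, "tau2": p.tau2, "tau": p.tau,
        "se_hk": p.se_hk, "method": p.method, "fallback": p.fallback,
        "n_pooled": p.q, "transform": p.transform,
        "ci": {"level": p.ci_level, "lower": p.ci_lower,
               "upper": p.ci_upper},
    }
    if pi is not None:
        d["pi"] = {"level": pi.level, "lower": pi.lower,
                   "upper": pi.upper, "defined": pi.defined}
    return d


def iecv_to_dict(result: IECVResult) -> dict:
    return {
        "terms": result.spec.term_names,
        "holdouts": [
            {
                "cluster": h.cluster,
                "coefficients": h.coefficients,
                "performance": {
                    m: {"value": e.value, "se": e.se, "n": e.n,
                        "events": e.events, "defined": e.defined}
                    for m, e in h.performance.items()
                },
            }
            for h in result.holdouts
        ],
        "pooled": {
            m: pooled_to_dict(p, result.intervals.get(m))
            for m, p in result.pooled.items()
        },
        "warnings": list(result.warnings),
    }


def trace_to_dict(trace: SIECVTrace) -> dict:
    return {
        "direction": trace.direction,
        "stopping_reason": trace.stopping_reason,
        "cycles": [
            {
                "cycle": c.cycle,
                "candidate_losses": c.candidate_losses,
                "selected": c.selected,
                "loss": c.loss,
                "skipped": c.skipped,
            }
            for c in trace.cycles
        ],
        "final_terms": trace.final_spec.term_names,
        "final_iecv": (iecv_to_dict(trace.final_iecv)
                       if trace.final_iecv else None),
        "warnings": list(trace.warnings),
    }


def global_model_to_dict(model: GlobalModel) -> dict:
    return {
        "terms": model.terms,
        "unshrunken": model.unshrunken,
        "shrunken": model.shrunken,
        "shrinkage_slope": model.shrinkage_slope,
        "intercept_correction": model.intercept_correction,
        "provenance": model.provenance,
    }


def render_forest_table(pooled: PooledEstimate, labels, values, ses,
                        pi: PredictionInterval | None = None) -> str:
    """TSV forest-plot table: cluster rows, summary row, PI row."""
    rows = forest_rows(labels, values, ses, pooled, pi,
                       z_level=pooled.ci_level)
    lines = ["\t".join(FOREST_COLUMNS)]
    for row in rows:
        lines.append("\t".join(
            f"{row[c]:.6g}" if isinstance(row[c], float) else str(row[c])
            for c in FOREST_COLUMNS
        ))
    return "\n".join(lines) + "\n"


def iecv_forest_tables(result: IECVResult) -> dict[str, str]:
    """One forest TSV per pooled metric of an IECV result."""
    tables = {}
    for metric, pooled in result.pooled.items():
        ests = [h.performance[metric] for h in result.holdouts
                if h.performance[metric].defined and h.performance[metric].se > 0]
        tables[metric] = render_forest_table(
            pooled, [e.cluster for e in ests], [e.value for e in ests],
            [e.se for e in ests], result.intervals.get(metric),
        )
    return tables


def run_report(config_echo: dict, trace: SIECVTrace,
               global_model: GlobalModel | None = None) -> dict:
    report = {
        "config": config_echo,
        "trace": trace_to_dict(trace),
    }
    if global_model is not None:
        report["global_model"] = global_model_to_dict(global_model)
    return report
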