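"""End-to-end recomputation of the headline thermal predictions.

Runs the shipped reference-calibrated configuration (one parameter set for
every quantity) and extracts the reported temperature summary: the
anterior surface maximum at 10 s and the per-layer maxima at 60 s for the
500 mA damage model, the surface rise above baseline, and the posterior
(posterior-stroma + endothelium) rise at the low clinical currents.
"""

from __future__ import annotations

from dataclasses import replace

from .bioheat import (
    delta_T,
    layer_max_temperatures,
    solve_protocol,
    surface_temperature,
)
from .config import CALIBRATED_CONFIG_NAME, RunConfig, load_packaged_config
from .electro import CurrentProtocol

__all__ = ["compute_targets", "REFERENCE_VALUES", "check_targets"]

#: Reference values for the pass/fail report of the `reproduce` command:
#: (value, comparison, relative tolerance).  "le"/"ge" are one-sided bounds.
REFERENCE_VALUES = {
    "t4": (82.1, "eq", 0.05),
    "t5": (146.0, "eq", 0.05),
    "t6": (100.0, "ge", 0.0),
    "t7": (48.2, "eq", 0.05),
    "t8": (42.7, "eq", 0.05),
    "t9": (48.0, "eq", 0.05),
    "t10": (0.2, "le", 0.0),
}


def compute_targets(config: RunConfig | None = None) -> dict[str, dict[str, float]]:
    """Recompute every reported thermal quantity from scratch.

    Returns ``{target_id: {"value": ..., "n": ...}}`` where ``n`` is the
    number of transient iterations of the underlying solve.  The solver is
    deterministic; no randomness enters these quantities.
    """
    cfg = config or load_packaged_config(CALIBRATED_CONFIG_NAME)
    baseline = cfg.solver.T_baseline_C

    extreme = solve_protocol(
        cfg.stack,
        CurrentProtocol(500.0, cfg.protocol.duration_s, cfg.protocol.report_times_s),
        cfg.solver,
        cfg.boundary,
    )
    m60 = layer_max_temperatures(extreme, 60.0)
    n = extreme.step_count

    # posterior rise at the low clinical currents, worst case over
    # 0.5/1/2 mA and 30/60 s
    post_rise = 0.0
    for i_mA in (0.5, 1.0, 2.0):
        fld = solve_protocol(
            cfg.stack,
            CurrentProtocol(i_mA, cfg.protocol.duration_s, cfg.protocol.report_times_s),
            cfg.solver,
            cfg.boundary,
        )
        for t in (30.0, 60.0):
            m = layer_max_temperatures(fld, t)
            post_rise = max(
                post_rise,
                m["posterior_stroma"] - baseline,
                m["endothelium"] - baseline,
            )

    return {
        "t4": {"value": surface_temperature(extreme, 10.0), "n": n},
        "t5": {"value": m60["epithelium"], "n": n},
        "t6": {"value": m60["tear_film"], "n": n},
        "t7": {"value": m60["posterior_stroma"], "n": n},
        "t8": {"value": m60["endothelium"], "n": n},
        "t9": {"value": delta_T(extreme, 10.0), "n": n},
        "t10": {"value": post_rise, "n": n},
    }


def check_targets(results: dict[str, dict[str, float]]) -> dict[str, bool]:
    """Compare recomputed values with the reference summary."""
    status = {}
    for tid, (ref, cmp, tol) in REFERENCE_VALUES.items():
        val = results[tid]["value"]
        if cmp == "eq":
            status[tid] = abs(val - ref) <= tol * abs(ref)
        elif cmp == "ge":
            status[tid] = val >= ref
        elif cmp == "le":
            status[tid] = val <= ref
        else:  # pragma: no cover
            raise ValueError(cmp)
    return status
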