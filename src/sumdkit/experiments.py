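"""Reference computational experiments on the built-in funnel system.

These fix the *study conditions* under which the package's headline claims
are measured, so tests, scripts and users all run the same experiment:

- system: :func:`sumdkit.model.build_receptor_model` defaults (50 beads,
  8 / 3 kcal/mol orthosteric / meta wells, 60 A box, Na+-like 23 amu ligand);
- thermostat: 310 K; friction 50 ps^-1 for binding experiments — in this
  implicit-solvent toy the Langevin friction stands in for solvent
  collisions, and 50 ps^-1 gives an ion diffusivity of ~0.2 A^2/ps, the
  physical ballpark for a solvated monatomic cation (the 1 ps^-1 engine
  default is a thermostat damping meant for simulations with explicit
  solvent friction);
- supervision: 200 ps ion windows, 5 A hand-off threshold, a budget of 50
  windows (10 ns attempted) per run.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .engine import EngineConfig, initial_state, run_segment
from .model import ToySystem, build_receptor_model
from .supervision import SupervisionConfig, first_binding_time, run_sumd, site_center

__all__ = ["reference_system", "binding_speedup"]

BINDING_FRICTION = 50.0  # ps^-1, solvent-emulating
BUDGET_WINDOWS = 50
WINDOW_PS = 200.0
THRESHOLD_A = 5.0


def reference_system(seed: int = 0) -> ToySystem:
    """The reference funnel system at its default construction parameters."""
    return build_receptor_model(seed=seed)


def binding_speedup(
    n_seeds: int = 20,
    base_seed: int = 0,
    *,
    friction: float = BINDING_FRICTION,
    budget_windows: int = BUDGET_WINDOWS,
    window_length: float = WINDOW_PS,
    threshold: float = THRESHOLD_A,
) -> dict:
    """Paired supervised-vs-unsupervised binding comparison.

    For each of ``n_seeds`` seeds, one supervised run (budget
    ``budget_windows`` windows of ``window_length`` ps) and one plain-MD run
    of the same attempted duration are launched on the same system. Returns
    bound counts, mean first-binding times (runs that never bind are censored
    at the budget, which under-states the supervised advantage), the
    speed-up ratio and a one-sided sign-test p-value on the discordant pairs.
    """
    system = reference_system()
    budget_ps = budget_windows * window_length
    center = site_center(system, system.site_definitions["orthosteric"])
    masses = system.ligand_masses

    sup_bound, unsup_bound = [], []
    sup_times, unsup_times = [], []
    for k in range(n_seeds):
        seed = base_seed + k
        engine_cfg = EngineConfig(friction=friction, seed=seed)
        sup_cfg = SupervisionConfig(
            window_length=window_length,
            threshold=threshold,
            max_total_windows=budget_windows,
            max_consecutive_failures=budget_windows,
        )
        result = run_sumd(system, engine_cfg, sup_cfg, seed=seed)
        sup_bound.append(result.termination == "bound")
        sup_times.append(
            result.first_binding_time
            if result.first_binding_time is not None
            else result.supervised_time
        )

        plain_cfg = EngineConfig(friction=friction, seed=seed)
        seg = run_segment(initial_state(system, plain_cfg), system, plain_cfg, budget_ps)
        t_bind = first_binding_time(seg.positions, seg.times, center, threshold, masses)
        unsup_bound.append(t_bind is not None)
        unsup_times.append(t_bind if t_bind is not None else budget_ps)

    sup_bound = np.asarray(sup_bound)
    unsup_bound = np.asarray(unsup_bound)
    b = int(np.sum(sup_bound & ~unsup_bound))
    c = int(np.sum(~sup_bound & unsup_bound))
    p_value = float(stats.binom.sf(b - 1, b + c, 0.5)) if b + c else 1.0
    mean_sup = float(np.mean(sup_times))
    mean_unsup = float(np.mean(unsup_times))
    return {
        "n_seeds": n_seeds,
        "supervised_bound": int(sup_bound.sum()),
        "unsupervised_bound": int(unsup_bound.sum()),
        "mean_supervised_first_binding_ps": mean_sup,
        "mean_unsupervised_first_binding_ps": mean_unsup,
        "speedup_ratio": mean_unsup / mean_sup,
        "p_value": p_value,
        "budget_ps": budget_ps,
    }
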