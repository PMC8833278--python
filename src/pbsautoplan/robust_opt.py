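"""Objective construction, scenario enumeration, and minimax spot-weight
optimization.

The composite objective is

    F(w) = sum of non-robust terms on the nominal dose
           + max over scenarios of the sum of robust terms,

each term a one-sided quadratic penalty of the dose-level violation,
normalized by structure volume and by prescription squared so weights are
comparable across structures. Optimization is projected subgradient descent
on the active worst-case scenario with backtracking line search (accepted
iterates are monotone in F); weights stay non-negative throughout.

Scenario families reproduce the perturbation combinatorics of robust
optimization with optional independent per-beam shifts:
count = (n_directions + 1)^(n_beams if independent else 1) * n_range_levels.
The clinical optimization family is 2 mm shifts right/left/superior/inferior
applied to all beams together with {-1%, 0, +1%} range scaling - 15
scenarios per iteration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .beamspot import MachineModel
from .core import Prescription, Scenario
from .dose_engine import InfluenceMatrix

__all__ = [
    "DIRECTION_VECTORS",
    "ScenarioFamily",
    "ObjectiveSpec",
    "OptimizerConfig",
    "enumerate_scenarios",
    "optimization_scenarios",
    "build_objectives",
    "optimize_weights",
    "enforce_mu_constraints",
]

#: patient-frame unit vectors for named shift directions
#: (x + toward patient left, y + anterior, z + superior)
DIRECTION_VECTORS = {
    "R": np.array([-1.0, 0.0, 0.0]),
    "L": np.array([1.0, 0.0, 0.0]),
    "A": np.array([0.0, 1.0, 0.0]),
    "P": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}


@dataclass
class ScenarioFamily:
    """A robust-optimization perturbation family."""

    shift_mm: float = 2.0
    directions: tuple[str, ...] = ("R", "L", "S", "I")
    independent_beams: bool = False
    n_beams: int = 4
    range_scales: tuple[float, ...] = (0.99, 1.0, 1.01)

    @property
    def count(self) -> int:
        base = len(self.directions) + 1  # each shift direction or no shift
        expo = self.n_beams if self.independent_beams else 1
        return base**expo * len(self.range_scales)


def enumerate_scenarios(family: ScenarioFamily) -> list[Scenario]:
    """Full Cartesian enumeration of a scenario family.

    The no-shift state is always included; with independent beams every beam
    independently takes each direction or none.
    """
    states: list[str | None] = [None] + list(family.directions)
    shifts: list[tuple[np.ndarray, dict[int, np.ndarray]]] = []
    if family.independent_beams:
        for combo in itertools.product(states, repeat=family.n_beams):
            per_beam = {
                b: family.shift_mm * DIRECTION_VECTORS[s]
                for b, s in enumerate(combo)
                if s is not None
            }
            shifts.append((np.zeros(3), per_beam))
    else:
        for s in states:
            t = np.zeros(3) if s is None else family.shift_mm * DIRECTION_VECTORS[s]
            shifts.append((t, {}))
    out = []
    for (t, pb), scale in itertools.product(shifts, family.range_scales):
        pb_tag = ",".join(f"b{b}" for b in sorted(pb)) if pb else ""
        tag = f"shift={np.array2string(t, precision=1)}{pb_tag} scale={scale:g}"
        out.append(Scenario(translation_mm=t, range_scale=scale, per_beam_mm=pb, tag=tag,
                            category="optimization"))
    assert len(out) == family.count
    return out


def optimization_scenarios() -> list[Scenario]:
    """The clinical 15-scenario optimization family (2 mm RLSI, +/-1% range)."""
    return enumerate_scenarios(ScenarioFamily())


# --------------------------------------------------------------------------
# objectives
# --------------------------------------------------------------------------

OBJECTIVE_KINDS = (
    "min_dose", "min_dvh", "max_dose", "max_dvh", "mean_dose", "dose_falloff", "per_beam_max"
)


@dataclass
class ObjectiveSpec:
    """One optimization objective."""

    kind: str
    structure: str
    dose_cge: float
    weight: float = 1.0
    robust: bool = False
    volume_pct: float | None = None  # for DVH kinds
    beam_index: int | None = None  # for per_beam_max
    # dose_falloff parameters: allowed dose ramps from dose_cge at the target
    # boundary down to low_dose_cge at falloff_distance_mm, constant beyond
    low_dose_cge: float | None = None
    falloff_distance_mm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind '{self.kind}'")
        if self.weight <= 0:
            raise ValueError("objective weight must be > 0")
        if self.kind in ("min_dvh", "max_dvh"):
            if self.volume_pct is None or not (0.0 < self.volume_pct <= 100.0):
                raise ValueError("DVH objectives need volume_pct in (0, 100]")
        if self.kind == "per_beam_max" and self.beam_index is None:
            raise ValueError("per_beam_max needs a beam_index")


#: default objective levels as fractions of prescription, and weights
DEFAULT_OBJECTIVE_PARAMS = {
    "target_weight": 400.0,
    "max_dose_weight": 10.0,
    "mean_dose_weight": 1.0,
    "ctv_min_dvh_level": 0.97,
    "ctv_min_dvh_volume_pct": 97.0,
    "external_max_robust": 1.10,
    "external_max_nominal": 1.05,
    "skin_rind_max": 0.75,
    "postneck_max": 0.55,
    "plexus_max": 1.00,
    "cord_max": 0.55,
    "brainstem_max": 0.50,
    "sfo_per_beam_max": 0.60,
    "falloff_low": 0.50,
    "falloff_distance_mm": 20.0,
}


def build_objectives(
    prescription: Prescription,
    predicted_means_cge: dict[str, float],
    anterior_beam_indices: tuple[int, ...],
    params: dict | None = None,
    target_name: str = "CTV50",
) -> list[ObjectiveSpec]:
    """The standard automated objective set.

    Target coverage (robust minimum dose at prescription and robust minimum
    DVH D97% > 97%), external dose fall-off plus robust and non-robust
    external maximum dose, skin rind / posterior neck / serial-OAR maximum
    doses, per-anterior-beam maximum dose on the supraclavicular SFO region,
    and predicted mean-dose objectives for the peripheral OARs (the esophagus
    never receives a predicted objective).
    """
    p = dict(DEFAULT_OBJECTIVE_PARAMS)
    p.update(params or {})
    P = prescription.dose_cge
    wt, wmax, wmean = p["target_weight"], p["max_dose_weight"], p["mean_dose_weight"]
    objs = [
        ObjectiveSpec("min_dose", target_name, P, weight=wt, robust=True),
        ObjectiveSpec("min_dvh", target_name, p["ctv_min_dvh_level"] * P, weight=wt,
                      robust=True, volume_pct=p["ctv_min_dvh_volume_pct"]),
        ObjectiveSpec("dose_falloff", "external_minus_target", P, weight=wmax,
                      low_dose_cge=p["falloff_low"] * P,
                      falloff_distance_mm=p["falloff_distance_mm"]),
        ObjectiveSpec("max_dose", "external", p["external_max_robust"] * P, weight=wmax,
                      robust=True),
        ObjectiveSpec("max_dose", "external", p["external_max_nominal"] * P, weight=wmax),
        ObjectiveSpec("max_dose", "skin_rind", p["skin_rind_max"] * P, weight=wmax),
        ObjectiveSpec("max_dose", "postneck", p["postneck_max"] * P, weight=wmax),
        ObjectiveSpec("max_dose", "brachial_plexus", p["plexus_max"] * P, weight=wmax),
        ObjectiveSpec("max_dose", "spinal_cord", p["cord_max"] * P, weight=wmax),
        ObjectiveSpec("max_dose", "brainstem", p["brainstem_max"] * P, weight=wmax),
    ]
    for b in anterior_beam_indices:
        objs.append(
            ObjectiveSpec("per_beam_max", "sfo_region", p["sfo_per_beam_max"] * P,
                          weight=wmax, beam_index=b)
        )
    if "esophagus" in predicted_means_cge:
        raise ValueError("the esophagus must not receive a predicted mean objective")
    for name, mean in predicted_means_cge.items():
        objs.append(ObjectiveSpec("mean_dose", name, float(mean), weight=wmean))
    return objs


# --------------------------------------------------------------------------
# objective evaluation on an influence matrix
# --------------------------------------------------------------------------


class _MatrixTerms:
    """Pre-resolved objective terms for one influence matrix's row set."""

    def __init__(
        self,
        influence: InfluenceMatrix,
        objectives: list[ObjectiveSpec],
        masks: dict[str, np.ndarray],
        prescription_cge: float,
        falloff_allowed: dict[str, np.ndarray] | None = None,
    ):
        self.influence = influence
        self.P = prescription_cge
        self.terms = []
        vox = influence.voxel_ids
        order = np.argsort(vox)
        for obj in objectives:
            mask = masks.get(obj.structure)
            if mask is None or not mask.any():
                raise KeyError(f"objective references missing structure '{obj.structure}'")
            flat = np.flatnonzero(mask.ravel())
            pos_sorted = np.searchsorted(vox, flat, sorter=order)
            ok = (pos_sorted < vox.size)
            cand = order[pos_sorted[ok]]
            hit = vox[cand] == flat[ok]
            rows = cand[hit]
            if rows.size == 0:
                continue  # structure has no voxels in this matrix's row set
            extra = None
            if obj.kind == "dose_falloff":
                allowed_full = (falloff_allowed or {})[obj.structure]
                extra = allowed_full[vox[rows]]
            self.terms.append((obj, rows, extra))

    def value_and_residual(self, weights: np.ndarray, robust: bool):
        """Objective value and residual dF/ddose for terms of one robustness class."""
        A = self.influence
        d = A.dose(weights)
        n_rows = d.size
        r = np.zeros(n_rows)
        beam_residuals: dict[int, np.ndarray] = {}
        total = 0.0
        P2 = self.P**2
        for obj, rows, extra in self.terms:
            if obj.robust != robust:
                continue
            if obj.kind == "per_beam_max":
                db = A.beam_dose(weights, obj.beam_index)[rows]
                viol = np.maximum(db - obj.dose_cge, 0.0)
                c = obj.weight / (rows.size * P2)
                total += c * float(viol @ viol)
                if viol.any():
                    rb = beam_residuals.setdefault(obj.beam_index, np.zeros(n_rows))
                    rb[rows] += 2.0 * c * viol
                continue
            dd = d[rows]
            c = obj.weight / (rows.size * P2)
            if obj.kind == "min_dose":
                viol = np.maximum(obj.dose_cge - dd, 0.0)
                total += c * float(viol @ viol)
                r[rows] -= 2.0 * c * viol
            elif obj.kind == "max_dose":
                viol = np.maximum(dd - obj.dose_cge, 0.0)
                total += c * float(viol @ viol)
                r[rows] += 2.0 * c * viol
            elif obj.kind == "dose_falloff":
                viol = np.maximum(dd - extra, 0.0)
                total += c * float(viol @ viol)
                r[rows] += 2.0 * c * viol
            elif obj.kind == "mean_dose":
                m = float(dd.mean())
                v = max(m - obj.dose_cge, 0.0)
                total += obj.weight * (v / self.P) ** 2
                if v > 0:
                    r[rows] += 2.0 * obj.weight * v / (P2 * rows.size)
            elif obj.kind in ("min_dvh", "max_dvh"):
                frac = obj.volume_pct / 100.0
                n = rows.size
                if obj.kind == "min_dvh":
                    # D_{v} must exceed the level: push up voxels below the level,
                    # excluding the coldest (1 - v) fraction, which may stay cold
                    n_allowed = int(np.floor((1.0 - frac) * n))
                    dv = np.partition(dd, n_allowed)[n_allowed] if n_allowed < n else -np.inf
                    sel = (dd < obj.dose_cge) & (dd >= dv)
                    viol = obj.dose_cge - dd[sel]
                    total += c * float(viol @ viol)
                    r[rows[sel]] -= 2.0 * c * viol
                else:
                    # at most v% may exceed the level: push down the hottest
                    # voxels above the level beyond the allowed count
                    n_allowed = int(np.floor(frac * n))
                    dv = np.partition(dd, n - n_allowed - 1)[n - n_allowed - 1] \
                        if n_allowed < n else np.inf
                    sel = (dd > obj.dose_cge) & (dd <= dv)
                    viol = dd[sel] - obj.dose_cge
                    total += c * float(viol @ viol)
                    r[rows[sel]] += 2.0 * c * viol
        return total, r, beam_residuals

    def gradient(self, r: np.ndarray, beam_residuals: dict[int, np.ndarray]) -> np.ndarray:
        A = self.influence
        g = A.matrix.T @ r
        for b, rb in beam_residuals.items():
            gb = A.matrix.T @ rb
            gb[A.spot_beams != b] = 0.0
            g = g + gb
        return np.asarray(g, dtype=float)


@dataclass
class OptimizerConfig:
    method: str = "lbfgs"  # lbfgs (smooth-max) | subgradient (active worst case)
    max_iterations: int = 500
    tolerance: float = 1e-5  # relative change of F between accepted iterates
    initial_step: float = 1.0
    max_backtracks: int = 25
    smoothmax_temperature_rel: float = 0.05  # tau as a fraction of the initial worst value


def optimize_weights(
    nominal: InfluenceMatrix,
    scenario_matrices: list[InfluenceMatrix],
    objectives: list[ObjectiveSpec],
    machine: MachineModel,
    masks: dict[str, np.ndarray],
    prescription: Prescription,
    config: OptimizerConfig | None = None,
    falloff_allowed: dict[str, np.ndarray] | None = None,
    target_name: str = "CTV50",
    initial_weights: np.ndarray | None = None,
):
    """Minimax spot-weight optimization.

    Non-robust terms are evaluated on the nominal influence matrix; robust
    terms on every scenario matrix. The default method smooths the max over
    scenarios with a log-sum-exp (temperature a small fraction of the initial
    worst-case value) and minimizes with bound-constrained L-BFGS; the
    ``subgradient`` method instead steps along the active worst scenario's
    subgradient with backtracking line search (accepted iterates are monotone
    in the exact minimax objective). Returns non-negative weights and a
    per-iteration convergence log. Non-convergence within the iteration
    budget returns the best iterate with a warning entry in the log, not an
    error.
    """
    import logging

    log = logging.getLogger(__name__)
    config = config or OptimizerConfig()
    nonrobust = [o for o in objectives if not o.robust]
    robust = [o for o in objectives if o.robust]
    nom_terms = _MatrixTerms(nominal, nonrobust, masks, prescription.dose_cge, falloff_allowed)
    scen_terms = [
        _MatrixTerms(m, robust, masks, prescription.dose_cge, falloff_allowed)
        for m in scenario_matrices
    ]
    if not scen_terms:
        raise ValueError("at least one scenario influence matrix is required")

    n_spots = nominal.matrix.shape[1]
    if initial_weights is not None:
        w = np.maximum(np.asarray(initial_weights, dtype=float), 0.0)
    else:
        # uniform weights scaled so the median target dose equals prescription
        w = np.ones(n_spots)
        ctv_rows = next(
            rows for obj, rows, _ in
            _MatrixTerms(nominal,
                         [ObjectiveSpec("min_dose", target_name, prescription.dose_cge)],
                         masks, prescription.dose_cge).terms
        )
        med = float(np.median(nominal.dose(w)[ctv_rows]))
        if med > 0:
            w *= prescription.dose_cge / med

    def evaluate(wv):
        fn, rn, bn = nom_terms.value_and_residual(wv, robust=False)
        vals = []
        parts = []
        for st in scen_terms:
            fs, rs, bs = st.value_and_residual(wv, robust=True)
            vals.append(fs)
            parts.append((rs, bs))
        worst = int(np.argmax(vals))
        return fn + vals[worst], (fn, rn, bn, worst, vals, parts)

    if config.method == "lbfgs":
        return _optimize_lbfgs(w, nom_terms, scen_terms, evaluate, config, log)
    if config.method != "subgradient":
        raise ValueError(f"unknown optimizer method '{config.method}'")

    F, info = evaluate(w)
    step = config.initial_step
    history = [{"iteration": 0, "objective": F, "step": 0.0,
                "worst_scenario": scen_terms[info[3]].influence.scenario.tag}]
    converged = False
    for it in range(1, config.max_iterations + 1):
        fn, rn, bn, worst, vals, parts = info
        g = nom_terms.gradient(rn, bn) + scen_terms[worst].gradient(*parts[worst])
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            converged = True
            break
        accepted = False
        a = step
        for _ in range(config.max_backtracks):
            w_new = np.maximum(w - a * g, 0.0)
            F_new, info_new = evaluate(w_new)
            if F_new < F:
                accepted = True
                break
            a *= 0.5
        if not accepted:
            converged = True
            break
        rel = (F - F_new) / max(F, 1e-300)
        w, F, info = w_new, F_new, info_new
        step = a * 2.0
        history.append({"iteration": it, "objective": F, "step": a,
                        "worst_scenario": scen_terms[info[3]].influence.scenario.tag})
        if rel < config.tolerance:
            converged = True
            break
    if not converged:
        log.warning("optimizer did not converge in %d iterations (best F=%.3e)",
                    config.max_iterations, F)
        history.append({"iteration": -1, "objective": F, "step": 0.0,
                        "worst_scenario": "warning: max iterations reached"})
    return w, history


def _optimize_lbfgs(w0, nom_terms, scen_terms, evaluate, config, log):
    """Smooth-max (log-sum-exp) realization of the minimax objective,
    minimized with bound-constrained L-BFGS."""
    from scipy.optimize import minimize
    from scipy.special import logsumexp, softmax

    _, info0 = evaluate(w0)
    tau = max(config.smoothmax_temperature_rel * max(info0[4]), 1e-9)

    def fun_and_grad(wv):
        fn, rn, bn = nom_terms.value_and_residual(wv, robust=False)
        vals, grads = [], []
        for st in scen_terms:
            fs, rs, bs = st.value_and_residual(wv, robust=True)
            vals.append(fs)
            grads.append(st.gradient(rs, bs))
        vals = np.asarray(vals)
        f = fn + tau * logsumexp(vals / tau)
        soft = softmax(vals / tau)
        g = nom_terms.gradient(rn, bn)
        for p, gs in zip(soft, grads):
            if p > 1e-12:
                g = g + p * gs
        last["exact"] = fn + float(vals.max())
        last["worst"] = int(np.argmax(vals))
        return f, g

    history: list[dict] = []
    last: dict = {}

    def cb(wv):
        history.append({"iteration": len(history) + 1, "objective": last["exact"],
                        "step": np.nan,
                        "worst_scenario": scen_terms[last["worst"]].influence.scenario.tag})

    F0, _ = evaluate(w0)
    history.append({"iteration": 0, "objective": F0, "step": 0.0,
                    "worst_scenario": scen_terms[info0[3]].influence.scenario.tag})
    res = minimize(
        fun_and_grad, w0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * w0.size,
        callback=cb,
        options={"maxiter": config.max_iterations, "ftol": config.tolerance * 1e-3,
                 "maxcor": 20},
    )
    if not res.success and res.status != 1:  # status 1 = iteration budget
        log.warning("L-BFGS-B stopped: %s", res.message)
    if res.status == 1:
        log.warning("optimizer did not converge in %d iterations", config.max_iterations)
        history.append({"iteration": -1, "objective": history[-1]["objective"], "step": 0.0,
                        "worst_scenario": "warning: max iterations reached"})
    return np.maximum(res.x, 0.0), history


def enforce_mu_constraints(weights: np.ndarray, machine: MachineModel) -> np.ndarray:
    """Deliverable-MU post-processing.

    Spots below half the minimum MU are deleted (weight 0); survivors are
    clipped up to the minimum MU and capped at ``max_min_mu_ratio`` times it,
    so the nonzero max/min ratio never exceeds the cap.
    """
    w = np.asarray(weights, dtype=float).copy()
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    mmin = machine.min_spot_mu
    w[w < mmin / 2.0] = 0.0
    nz = w > 0
    if not nz.any():
        raise ValueError("MU constraints deleted every spot")
    w[nz] = np.clip(w[nz], mmin, machine.max_min_mu_ratio * mmin)
    return w
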