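"""Joint activity–attenuation estimation schedules.

Alternating schedules update the activity λ and the electron density ρ
with the current estimate of the respective other quantity:

* **2-algorithm** (low attenuation): per iteration, 10 sub-iterations of
  attenuation-corrected trues-OSEM (4 subsets) updating λ, then 10
  sub-iterations of scatter-MLGA (4 SOR subsets) updating ρ — 20
  sub-iterations per iteration.  MLEM-OSL can replace MLGA as the
  attenuation block at the cost of convergence speed.
* **4-algorithm** (any attenuation): per iteration, in order,
  scatter-MLEM(λ), trues-MLEM(λ), scatter-MLGA(ρ), trues-MLTR(ρ, η = 0.03);
  two sub-iterations per iteration, no subsets.
* **MLAA baseline**: alternating single trues-MLEM and trues-MLTR updates
  from trues data only.  Without scatter, the joint trues likelihood has an
  extended nonunique maximum (activity-scaling/attenuation-offset
  crosstalk), and MLAA can converge to an apparent local maximum; the
  4-algorithm initialized at that point uses the scattered data to escape.

Traces record per-sub-iteration NMSEs, the apparent likelihoods (both
quantities estimated), and — when the truth is available — the ideal
likelihoods (counterpart quantity fixed at its true value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emission import (
    partition_subsets,
    scatter_mlem_update,
    trues_mlem_update,
    trues_mltr_update,
)
from .forward import forward_scatter, forward_trues, poisson_loglik
from .metrics import nmse
from .s2a import StepSizeSpec, mlem_osl_update, mlga_update
from .systems import ScatterSystem, TruesSystem, a_pair_values

__all__ = [
    "Schedule",
    "JointState",
    "ReconTrace",
    "track_likelihoods",
    "run_2algorithm",
    "run_4algorithm",
    "run_mlaa",
    "run_crosstalk_escape",
    "single_voxel_joint_surface",
]

#: Default MLGA step-size constant inside joint schedules: half the
#: standalone default, re-derated for stability of the alternating updates
#: (the activity estimate the scatter gradient sees is itself in flux).
JOINT_GAMMA = 0.25

#: MLAA plateau detector: relative change of the apparent trues
#: log-likelihood below this over PLATEAU_WINDOW consecutive iterations.
PLATEAU_RTOL = 1e-8
PLATEAU_WINDOW = 20


@dataclass(frozen=True)
class Schedule:
    """Ordered (algorithm, n_repeats, n_subsets) steps of one iteration."""

    steps: tuple

    @property
    def sub_iterations_per_iteration(self) -> int:
        return sum(rep for _, rep, _ in self.steps)


TWO_ALGORITHM = Schedule((("trues-OSEM", 10, 4), ("scatter-MLGA", 10, 4)))
FOUR_ALGORITHM = Schedule((("scatter-MLEM+trues-MLEM", 1, 1),
                           ("scatter-MLGA+trues-MLTR", 1, 1)))
MLAA = Schedule((("trues-MLEM", 1, 1), ("trues-MLTR", 1, 1)))


@dataclass
class JointState:
    """Current (λ, ρ) estimates and iteration counter."""

    lam: np.ndarray
    rho: np.ndarray
    iteration: int = 0
    diverged: bool = False
    divergence_iteration: int | None = None


class ReconTrace:
    """Per-sub-iteration record of estimates, NMSEs, and likelihoods."""

    def __init__(self, store_images: bool = False):
        self.rows: list[dict] = []
        self.images: list[tuple[np.ndarray, np.ndarray]] = []
        self.store_images = store_images

    def append(self, lam=None, rho=None, **row) -> None:
        self.rows.append(row)
        if self.store_images and lam is not None:
            self.images.append((lam.copy(), rho.copy()))

    def column(self, name: str) -> np.ndarray:
        return np.array([r.get(name, np.nan) for r in self.rows], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def track_likelihoods(scatter: ScatterSystem, trues: TruesSystem, y, z,
                      lam_est, rho_est, lam_true=None, rho_true=None) -> dict:
    """The four tracked likelihood values at the current estimates.

    Apparent likelihoods use both estimates (what the optimizers see);
    ideal likelihoods fix the counterpart quantity at its true value and
    require the truth images (absent truth, they are reported as NaN).
    """
    out = {
        "ll_app_scatt": poisson_loglik(
            y, forward_scatter(scatter, lam_est, rho_est)),
        "ll_app_trues": poisson_loglik(
            z, forward_trues(trues, lam_est, rho_est)),
        "ll_att_scatt": np.nan,
        "ll_act_scatt": np.nan,
    }
    if lam_true is not None:
        out["ll_att_scatt"] = poisson_loglik(
            y, forward_scatter(scatter, lam_true, rho_est))
    if rho_true is not None:
        out["ll_act_scatt"] = poisson_loglik(
            y, forward_scatter(scatter, lam_est, rho_true))
    return out


def _record(trace, state, scatter, trues, y, z, lam_true, rho_true,
            sub_iter, algorithm, track):
    row = {"sub_iter": sub_iter, "algorithm": algorithm}
    if lam_true is not None:
        row["nmse_lambda"] = nmse(state.lam, lam_true)
    if rho_true is not None:
        row["nmse_rho"] = nmse(state.rho, rho_true)
    if track:
        row.update(track_likelihoods(scatter, trues, y, z, state.lam,
                                     state.rho, lam_true, rho_true))
    trace.append(lam=state.lam, rho=state.rho, **row)


def _guard(state: JointState, sub_iter: int) -> bool:
    """Divergence guard: halt (returning True) on non-finite estimates."""
    if not (np.all(np.isfinite(state.lam)) and np.all(np.isfinite(state.rho))):
        state.diverged = True
        state.divergence_iteration = sub_iter
        return True
    return False


def run_2algorithm(scatter: ScatterSystem, trues: TruesSystem, y, z,
                   lam0, rho0, n_iterations: int,
                   n_subsets: int = 4, inner: int = 10,
                   gamma: float = JOINT_GAMMA,
                   s2a_algorithm: str = "mlga",
                   lam_true=None, rho_true=None,
                   track_likelihoods_every: int = 1,
                   store_images: bool = False):
    """Low-attenuation 2-algorithm: (trues-OSEM^10_4) + (scatter-MLGA^10_4),
    20 sub-iterations per iteration.

    ``s2a_algorithm="mlem_osl"`` swaps the attenuation block for full-data
    MLEM-OSL sub-iterations (drop-in replacement for low attenuation).
    """
    if s2a_algorithm not in ("mlga", "mlem_osl"):
        raise ValueError("s2a_algorithm must be 'mlga' or 'mlem_osl'")
    state = JointState(lam=np.asarray(lam0, float).copy(),
                       rho=np.asarray(rho0, float).copy())
    trace = ReconTrace(store_images=store_images)
    lor_part = partition_subsets(trues.n_lors, n_subsets,
                                 angular_key=trues.lor_d1)
    sor_part = partition_subsets(scatter.n_sors, n_subsets,
                                 angular_key=scatter.sor_ds)
    sor_masks = [sor_part.mask(s) for s in range(n_subsets)]
    lor_rows = [lor_part.rows(s) for s in range(n_subsets)]
    step = StepSizeSpec(mode="mlem_like", constant=gamma)
    sub = 0
    for it in range(n_iterations):
        for _ in range(inner):
            for rows in lor_rows:
                state.lam = trues_mlem_update(trues, state.lam, state.rho, z,
                                              rows=rows)
            sub += 1
            _record(trace, state, scatter, trues, y, z, lam_true, rho_true,
                    sub, "trues-OSEM",
                    track=(sub % track_likelihoods_every == 0))
            if _guard(state, sub):
                return state, trace
        a_vals = a_pair_values(scatter, state.lam)
        for _ in range(inner):
            if s2a_algorithm == "mlga":
                for mask in sor_masks:
                    state.rho = mlga_update(scatter, a_vals, state.rho, y,
                                            step=step, rows_mask=mask)
                label = "scatter-MLGA"
            else:
                state.rho = mlem_osl_update(scatter, a_vals, state.rho, y)
                label = "scatter-MLEM-OSL"
            sub += 1
            _record(trace, state, scatter, trues, y, z, lam_true, rho_true,
                    sub, label, track=(sub % track_likelihoods_every == 0))
            if _guard(state, sub):
                return state, trace
        state.iteration = it + 1
    return state, trace


def run_4algorithm(scatter: ScatterSystem, trues: TruesSystem, y, z,
                   lam0, rho0, n_iterations: int,
                   eta: float = 0.03, gamma: float = JOINT_GAMMA,
                   lam_true=None, rho_true=None,
                   track_likelihoods_every: int = 1,
                   store_images: bool = False):
    """High-attenuation 4-algorithm:
    (scatter-MLEM + trues-MLEM) + (scatter-MLGA + trues-MLTR), two
    sub-iterations per iteration, no subsets; the trues-MLEM update uses λ
    as already updated by the preceding scatter-MLEM update."""
    state = JointState(lam=np.asarray(lam0, float).copy(),
                       rho=np.asarray(rho0, float).copy())
    trace = ReconTrace(store_images=store_images)
    step = StepSizeSpec(mode="mlem_like", constant=gamma)
    sub = 0
    for it in range(n_iterations):
        state.lam = scatter_mlem_update(scatter, state.lam, state.rho, y)
        state.lam = trues_mlem_update(trues, state.lam, state.rho, z)
        sub += 1
        _record(trace, state, scatter, trues, y, z, lam_true, rho_true,
                sub, "scatter-MLEM+trues-MLEM",
                track=(sub % track_likelihoods_every == 0))
        if _guard(state, sub):
            return state, trace
        a_vals = a_pair_values(scatter, state.lam)
        state.rho = mlga_update(scatter, a_vals, state.rho, y, step=step)
        state.rho = trues_mltr_update(trues, state.rho, state.lam, z, eta=eta)
        sub += 1
        _record(trace, state, scatter, trues, y, z, lam_true, rho_true,
                sub, "scatter-MLGA+trues-MLTR",
                track=(sub % track_likelihoods_every == 0))
        if _guard(state, sub):
            return state, trace
        state.iteration = it + 1
    return state, trace


def run_mlaa(trues: TruesSystem, z, lam0, rho0, n_iterations: int,
             eta: float = 0.03, lam_true=None, rho_true=None,
             scatter: ScatterSystem | None = None, y=None,
             stop_at_plateau: bool = True,
             plateau_rtol: float = PLATEAU_RTOL,
             plateau_window: int = PLATEAU_WINDOW,
             store_images: bool = False):
    """Traditional MLAA: alternating trues-MLEM¹₁ + trues-MLTR¹₁ from trues
    data only.

    A plateau detector flags apparent convergence when the relative change
    of the apparent trues log-likelihood stays below ``plateau_rtol`` over
    ``plateau_window`` consecutive iterations; with ``stop_at_plateau`` the
    run halts there.  A scatter system may be supplied purely for
    likelihood bookkeeping in the trace (MLAA itself never uses it).

    Returns (state, trace, plateau_iteration) with plateau_iteration = None
    if never detected.
    """
    state = JointState(lam=np.asarray(lam0, float).copy(),
                       rho=np.asarray(rho0, float).copy())
    trace = ReconTrace(store_images=store_images)
    ll_hist: list[float] = []
    plateau_at = None
    sub = 0
    for it in range(n_iterations):
        state.lam = trues_mlem_update(trues, state.lam, state.rho, z)
        sub += 1
        _mlaa_record(trace, state, trues, z, lam_true, rho_true, sub,
                     "trues-MLEM", scatter, y)
        state.rho = trues_mltr_update(trues, state.rho, state.lam, z, eta=eta)
        sub += 1
        ll = _mlaa_record(trace, state, trues, z, lam_true, rho_true, sub,
                          "trues-MLTR", scatter, y)
        if _guard(state, sub):
            break
        ll_hist.append(ll)
        if plateau_at is None and len(ll_hist) > plateau_window:
            recent = np.array(ll_hist[-(plateau_window + 1):])
            rel = np.abs(np.diff(recent)) / max(abs(recent[-1]), 1e-300)
            if np.all(rel < plateau_rtol):
                plateau_at = it + 1
                if stop_at_plateau:
                    state.iteration = it + 1
                    break
        state.iteration = it + 1
    return state, trace, plateau_at


def _mlaa_record(trace, state, trues, z, lam_true, rho_true, sub, algorithm,
                 scatter, y):
    row = {"sub_iter": sub, "algorithm": algorithm}
    if lam_true is not None:
        row["nmse_lambda"] = nmse(state.lam, lam_true)
    if rho_true is not None:
        row["nmse_rho"] = nmse(state.rho, rho_true)
    ll = poisson_loglik(z, forward_trues(trues, state.lam, state.rho))
    row["ll_app_trues"] = ll
    if scatter is not None and y is not None:
        row["ll_app_scatt"] = poisson_loglik(
            y, forward_scatter(scatter, state.lam, state.rho))
    trace.append(lam=state.lam, rho=state.rho, **row)
    return ll


def run_crosstalk_escape(scatter: ScatterSystem, trues: TruesSystem, y, z,
                         lam0, rho0,
                         n_mlaa_iterations: int = 2000,
                         n_escape_iterations: int = 500,
                         eta: float = 0.03, gamma: float = JOINT_GAMMA,
                         lam_true=None, rho_true=None,
                         track_likelihoods_every: int = 1):
    """MLAA-to-4-algorithm crosstalk-escape experiment.

    Runs MLAA from the standard initial guesses until its apparent-trues-LL
    plateau, then initializes the 4-algorithm at the MLAA fixed point and
    continues with the scattered data included.  Returns a dict with both
    traces, the plateau NMSEs, and the final state.
    """
    mlaa_state, mlaa_trace, plateau_at = run_mlaa(
        trues, z, lam0, rho0, n_mlaa_iterations, eta=eta,
        lam_true=lam_true, rho_true=rho_true, scatter=scatter, y=y)
    plateau = {
        "plateau_iteration": plateau_at,
        "nmse_rho": nmse(mlaa_state.rho, rho_true) if rho_true is not None
        else np.nan,
        "nmse_lambda": nmse(mlaa_state.lam, lam_true) if lam_true is not None
        else np.nan,
    }
    esc_state, esc_trace = run_4algorithm(
        scatter, trues, y, z, mlaa_state.lam, mlaa_state.rho,
        n_escape_iterations, eta=eta, gamma=gamma,
        lam_true=lam_true, rho_true=rho_true,
        track_likelihoods_every=track_likelihoods_every)
    return {
        "mlaa_state": mlaa_state,
        "mlaa_trace": mlaa_trace,
        "plateau": plateau,
        "escape_state": esc_state,
        "escape_trace": esc_trace,
    }


def single_voxel_joint_surface(rho_true: float, lam_true: float = 1.0,
                               b: float = 1.0, k: float = 1.0,
                               u: float = 1.0,
                               lam_grid=None, rho_grid=None,
                               normalize: bool = False) -> dict:
    """Log-likelihood surfaces of the single-voxel, single-detector-pair
    joint problem with expected data z̄ = (uλ)e^{−uρ} and
    ȳ = (bλ)e^{−kρ}ρ.

    Returns the trues, scatter, and joint LL surfaces over the (λ, ρ)
    candidate grids, the grid argmax of the joint surface, and the expected
    counts at the truth.  With ``normalize`` each surface is affinely
    mapped to [−1, 0].
    """
    lam_grid = np.linspace(0.05, 3.0, 120) if lam_grid is None \
        else np.asarray(lam_grid, float)
    rho_grid = np.linspace(0.01, 4.0, 160) if rho_grid is None \
        else np.asarray(rho_grid, float)
    y = b * lam_true * np.exp(-k * rho_true) * rho_true
    z = u * lam_true * np.exp(-u * rho_true)

    L, R = np.meshgrid(lam_grid, rho_grid, indexing="ij")
    ybar = b * L * np.exp(-k * R) * R
    zbar = u * L * np.exp(-u * R)
    ll_scatter = y * np.log(ybar) - ybar
    ll_trues = z * np.log(zbar) - zbar
    ll_joint = ll_scatter + ll_trues

    if normalize:
        def _norm(s):
            lo, hi = np.min(s), np.max(s)
            return (s - hi) / (hi - lo) if hi > lo else np.zeros_like(s)
        ll_scatter, ll_trues, ll_joint = map(_norm,
                                             (ll_scatter, ll_trues, ll_joint))

    i, j = np.unravel_index(np.argmax(ll_joint), ll_joint.shape)
    return {
        "lam_grid": lam_grid,
        "rho_grid": rho_grid,
        "ll_scatter": ll_scatter,
        "ll_trues": ll_trues,
        "ll_joint": ll_joint,
        "joint_argmax": (float(lam_grid[i]), float(rho_grid[j])),
        "ybar_true": float(y),
        "zbar_true": float(z),
    }
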