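"""Deterministic ODE model of inhibited lipid autoxidation.

The reaction network (all concentrations M, time s)::

    initiation      -> LOO*                      zeroth order, rate R_i
    LOO* + LH       -> LOOH + L*                 k_p      (propagation, H abstraction)
    L*   + O2       -> LOO*                      k_O2     (O2 addition; the measured uptake)
    LOO* + LOO*     -> non-radical products      2k_t     (radical removal rate 2k_t[LOO*]^2)
    LOO* + X_g      -> LOOH + X_g*               k_inh    (inhibition, H-atom transfer)
    LOO* + X_g*     -> non-radical products      k_cross  (cross-termination)
    X_g* + X_g*     -> inert                     2k_ArO*  (phenoxyl self-decay, pseudo-phase)
    X_g* + X_g*     -> dimer (2 phenols of X_{g+1})  k_dim  (coupling, pseudo-phase)
    ArO* + X'_0     -> ArOH + X'_0*              k_r      (regeneration, pseudo-phase)
    X_g             -> inert                     k_dec    (antioxidant decomposition)

``X_g`` denotes the pool of trapping-competent *phenol equivalents* of an
antioxidant at coupling generation ``g``: the parent compound is generation
0; each coupling event consumes two generation-``g`` phenoxyls and recovers
two trapping-competent phenols on the resulting dimer (generation ``g+1``),
so the phenol-unit count is conserved through coupling while the trapping
capacity of the roster grows.  Phenoxyls of the deepest instantiated
generation terminate by reactions 6+7 like any monophenol (with
``cascade_depth`` = 0 the unmodeled dimer is an inert sink and coupling
merely removes radicals).

Reactions marked "pseudo-phase" occur between species co-localized in the
lipid/surfactant pseudo-phase; their bulk rate constants are divided by the
medium's lipid volume fraction (``interface_factor``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (GenerationError, IntegrationFailure,
                     OracleUndefinedError)
from .params import ExperimentSystem, ReactionParameters
from .trace import Trace

__all__ = [
    "ReactionNetwork", "SimulationResult", "simulate", "steady_state_rox",
    "closed_form_uptake", "inhibited_rate_oracle", "effective_stoichiometry",
]

# fixed state-vector slots ahead of the antioxidant block
_LH, _L, _LOO, _UPTAKE, _LOOH, _TERM, _TERMLOO = range(7)
_N_FIXED = 7


class ReactionNetwork:
    """State-vector layout and right-hand side for one experiment."""

    def __init__(self, system: ExperimentSystem, params: ReactionParameters):
        self.system = system
        self.params = params
        f = system.resolved_interface_factor
        if f <= 0:
            raise ValueError("interface_factor must be > 0")
        # Pseudo-phase kinetics: concentrations are bulk-referenced, but the
        # reactants of every bimolecular lipid-phase step share the lipid
        # volume fraction f, so molecular rate constants act as k/f.  k_p and
        # k_inh as conventionally reported are already the molecular values
        # (f cancels in the rate observables they are derived from), whereas
        # the reported peroxyl self-termination is the *apparent* constant
        # 2k_t,app = f * 2k_t,mol; hence the 1/f^2.  With this convention the
        # closed-form oracles k_p [LH] sqrt(R_i/2k_t) and
        # k_p [LH] R_i / (2 k_inh [ArOH]) hold with the reported constants
        # independently of f.
        self.k_p_eff = params.k_p / f
        self.two_kt_eff = params.two_kt / f ** 2
        self.two_k_AO_eff = params.two_k_AO / f
        self.k_r_eff = params.k_r / f
        self.k_dim_eff = params.k_dim / f

        # one (phenol pool, phenoxyl pool) pair per antioxidant generation
        unit_names: list[str] = []
        kinh, kcross, kdec, couple, nxt = [], [], [], [], []
        self._parent_unit: dict[str, int] = {}
        for ax in system.antioxidants:
            depth = ax.cascade_depth if ax.dimerizes else 0
            kc = ax.resolved_k_cross(params) / f
            kd = ax.resolved_k_dec(params)
            base = len(unit_names)
            self._parent_unit[ax.name] = base
            for g in range(depth + 1):
                unit_names.append(ax.name if g == 0 else f"{ax.name}_dim{g}")
                kinh.append((ax.k_inh if g == 0 else ax.dimer_k_inh) / f)
                kcross.append(kc)
                kdec.append(kd)
                # phenoxyls couple into the next explicit dimer generation;
                # the deepest modeled generation terminates by reactions
                # 6+7 instead (except depth 0, where the unmodeled dimer is
                # an inert sink and coupling merely removes radicals)
                couple.append(ax.dimerizes and (g < depth or depth == 0))
                nxt.append(base + g + 1 if (ax.dimerizes and g < depth) else -1)
        self.unit_names = unit_names
        self.n_units = len(unit_names)
        self._kinh = np.asarray(kinh, dtype=float)
        self._kcross = np.asarray(kcross, dtype=float)
        self._kdec = np.asarray(kdec, dtype=float)
        self._couple = np.asarray(couple, dtype=bool)
        self._next = np.asarray(nxt, dtype=int)

        # regeneration pairs: (radical of regenerable, donor phenol pool,
        # donor radical pool, parent pool of regenerable).  Every
        # closed-shell phenol unit of a co-antioxidant -- parent or
        # recovered dimer hydroxyl -- can donate the H atom.
        self._regen: list[tuple[int, int, int, int]] = []
        if params.k_r > 0:
            for ax in system.antioxidants:
                if not ax.regenerable:
                    continue
                u = self._parent_unit[ax.name]
                for other in system.antioxidants:
                    if other.name == ax.name:
                        continue
                    depth = other.cascade_depth if other.dimerizes else 0
                    v0 = self._parent_unit[other.name]
                    for g in range(depth + 1):
                        self._regen.append((self.radical_index(u),
                                            self.pool_index(v0 + g),
                                            self.radical_index(v0 + g),
                                            self.pool_index(u)))

        self.n_state = _N_FIXED + 2 * self.n_units + (0 if system.O2_clamped else 1)
        self._o2_index = None if system.O2_clamped else self.n_state - 1

    # -- state-vector bookkeeping -------------------------------------------

    def pool_index(self, unit: int) -> int:
        return _N_FIXED + 2 * unit

    def radical_index(self, unit: int) -> int:
        return _N_FIXED + 2 * unit + 1

    @property
    def species_names(self) -> list[str]:
        names = ["LH", "L", "LOO", "uptake", "LOOH",
                 "terminated_radicals", "terminated_LOO"]
        for u in self.unit_names:
            names.extend([u, u + "_rad"])
        if self._o2_index is not None:
            names.append("O2")
        return names

    def initial_state(self, inhibitors: bool = True) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        y0[_LH] = self.system.LH0
        unit = 0
        for ax in self.system.antioxidants:
            depth = ax.cascade_depth if ax.dimerizes else 0
            if inhibitors:
                y0[self.pool_index(unit)] = ax.conc0
            unit += depth + 1
        if self._o2_index is not None:
            y0[self._o2_index] = self.system.O2_0
        return y0

    def add_inhibitors(self, y: np.ndarray) -> np.ndarray:
        """Return a copy of ``y`` with the antioxidant roster injected."""
        y = y.copy()
        unit = 0
        for ax in self.system.antioxidants:
            depth = ax.cascade_depth if ax.dimerizes else 0
            y[self.pool_index(unit)] += ax.conc0
            unit += depth + 1
        return y

    # -- dynamics ------------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        s = self.system
        LH, L, LOO = y[_LH], y[_L], y[_LOO]
        O2 = s.O2_0 if self._o2_index is None else y[self._o2_index]

        dy = np.zeros_like(y)
        v_p = self.k_p_eff * LOO * LH
        v_o2 = p.k_O2 * L * O2
        v_t = self.two_kt_eff * LOO * LOO   # LOO* removal rate (2 per event)

        dy[_LH] = -v_p
        dy[_L] = v_p - v_o2
        dy[_LOO] = s.R_i - v_p + v_o2 - v_t
        dy[_UPTAKE] = v_o2 + (s.R_i if p.include_initiator_O2 else 0.0)
        dy[_LOOH] = v_p
        dy[_TERM] = v_t
        dy[_TERMLOO] = v_t
        if self._o2_index is not None:
            dy[self._o2_index] = -v_o2

        if self.n_units:
            X = y[_N_FIXED:_N_FIXED + 2 * self.n_units:2]
            XR = y[_N_FIXED + 1:_N_FIXED + 1 + 2 * self.n_units:2]
            v_hat = self._kinh * LOO * X
            v_cross = self._kcross * LOO * XR
            v_self = self.two_k_AO_eff * XR * XR     # radical removal rate
            v_couple = np.where(self._couple, self.k_dim_eff * XR * XR, 0.0)

            dX = -v_hat - self._kdec * X
            dXR = v_hat - v_cross - v_self - 2.0 * v_couple
            for u in np.nonzero(v_couple)[0]:
                tgt = self._next[u]
                if tgt >= 0:
                    dX[tgt] += 2.0 * v_couple[u]

            for (rr, xd, rd, xr) in self._regen:
                v = self.k_r_eff * y[rr] * y[xd]
                dy[rr] -= v
                dy[xr] += v
                dy[xd] -= v
                dy[rd] += v

            dy[_LOO] -= v_hat.sum() + v_cross.sum()
            dy[_LOOH] += v_hat.sum()
            dy[_TERM] += 2.0 * v_cross.sum() + v_self.sum() + 2.0 * v_couple.sum()
            dy[_TERMLOO] += v_cross.sum()
            dy[_N_FIXED:_N_FIXED + 2 * self.n_units:2] += dX
            dy[_N_FIXED + 1:_N_FIXED + 1 + 2 * self.n_units:2] += dXR
        return dy

    def integrate(self, t_span, y0, t_eval=None, events=None,
                  rtol: float = 1.0e-8, atol: float = 1.0e-15):
        sol = solve_ivp(self.rhs, t_span, y0, method="LSODA", t_eval=t_eval,
                        events=events, rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise IntegrationFailure(f"ODE integration failed: {sol.message}")
        self._check_state(sol.y)
        return sol

    def _check_state(self, ys: np.ndarray) -> None:
        names = self.species_names
        if not np.all(np.isfinite(ys)):
            i = int(np.argwhere(~np.isfinite(ys))[0][0])
            raise IntegrationFailure(f"non-finite state for species {names[i]!r}")
        floor = -1.0e-9 * max(1.0e-6, float(np.nanmax(ys)))
        mins = ys.min(axis=1)
        if mins.min() < floor:
            i = int(np.argmin(mins))
            raise IntegrationFailure(
                f"negative concentration for species {names[i]!r} "
                f"({mins[i]:.3e} M)")


@dataclass
class SimulationResult:
    """Trace plus the full species ledger of one simulation."""

    trace: Trace
    species: pd.DataFrame          # one column per species, indexed by time

    def radical_balance_error(self) -> float:
        """Max abs deviation of R_i*t from radicals present + terminated (M)."""
        df = self.species
        R_i = float(self.trace.metadata.get("R_i"))
        t_inj = self.trace.injection_time
        present = df["L"] + df["LOO"]
        present = present + df[[c for c in df.columns if c.endswith("_rad")]].sum(axis=1)
        supplied = R_i * df.index.to_numpy()
        return float(np.abs(supplied - (present + df["terminated_radicals"])).max())

    def o2_ledger_error(self) -> float:
        """Max abs deviation of the O2 ledger identity (M).

        Every O2 taken up (plus initiator-derived peroxyls when those are
        not counted in the uptake) must reside in LOOH, in live
        chain-carriers, or in terminated LOO-derived products.
        """
        df = self.species
        R_i = float(self.trace.metadata.get("R_i"))
        include = bool(self.trace.metadata.get("include_initiator_O2", False))
        t = df.index.to_numpy()
        supplied = df["uptake"] + (0.0 if include else R_i * t)
        held = df["LOOH"] + df["LOO"] + df["terminated_LOO"]
        return float(np.abs(supplied - held).max())


def _injection_event(network: ReactionNetwork, threshold: float):
    def event(t, y):
        return y[_UPTAKE] - threshold
    event.terminal = True
    event.direction = 1.0
    return event


def simulate(system: ExperimentSystem, params: ReactionParameters,
             t_end: float, dt_out: float = 5.0, injection=None,
             rtol: float = 1.0e-8, atol: float = 1.0e-15,
             return_ledger: bool = False):
    """Integrate the reaction network and return a noiseless uptake trace.

    Parameters
    ----------
    t_end, dt_out : float
        Simulated duration and output sampling interval (s).
    injection : None, "auto" or float
        ``None`` places the antioxidant roster in the system from t = 0.
        ``"auto"`` runs the uninhibited system until 10% of ``O2_0`` has
        been consumed and injects the roster at that instant, mirroring
        the experimental protocol; a float injects at that time (s).
    return_ledger : bool
        If True return a :class:`SimulationResult` carrying the full
        species ledger; otherwise return the :class:`Trace` alone.

    Raises
    ------
    IntegrationFailure
        On non-finite or negative state (the message names the species).
    GenerationError
        If ``injection="auto"`` and 10% O2 depletion is not reached
        before ``t_end``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if not system.antioxidants and params.two_kt <= 0:
        raise ValueError("two_kt must be > 0 for an uninhibited simulation")

    net = ReactionNetwork(system, params)
    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    if t_grid[-1] > t_end:
        t_grid[-1] = t_end

    if injection is None or not system.antioxidants:
        t_inj = 0.0
        sol = net.integrate((0.0, t_end), net.initial_state(inhibitors=True),
                            t_eval=t_grid, rtol=rtol, atol=atol)
        times, ys = sol.t, sol.y
    else:
        y0 = net.initial_state(inhibitors=False)
        if injection == "auto":
            ev = _injection_event(net, 0.10 * system.O2_0)
            pre = net.integrate((0.0, t_end), y0, events=ev,
                                rtol=rtol, atol=atol)
            if not pre.t_events[0].size:
                raise GenerationError(
                    "t_end reached before 10% O2 depletion; no injection point")
            t_inj = float(pre.t_events[0][0])
            y_inj = pre.y_events[0][0]
        else:
            t_inj = float(injection)
            if not 0.0 <= t_inj < t_end:
                raise ValueError("injection time must lie in [0, t_end)")
            pre = net.integrate((0.0, t_inj), y0, rtol=rtol, atol=atol) \
                if t_inj > 0 else None
            y_inj = pre.y[:, -1] if pre is not None else y0
        # resample the pre-injection phase on the output grid
        pre_grid = t_grid[t_grid <= t_inj]
        if pre_grid.size:
            sol1 = net.integrate((0.0, max(t_inj, pre_grid[-1])), y0,
                                 t_eval=pre_grid, rtol=rtol, atol=atol)
            ys1 = sol1.y
        else:
            ys1 = np.empty((net.n_state, 0))
        post_grid = t_grid[t_grid > t_inj]
        y_post0 = net.add_inhibitors(y_inj)
        sol2 = net.integrate((t_inj, t_end), y_post0,
                             t_eval=post_grid if post_grid.size else None,
                             rtol=rtol, atol=atol)
        ys2 = sol2.y[:, :post_grid.size] if post_grid.size else \
            np.empty((net.n_state, 0))
        times = np.concatenate([pre_grid, post_grid])
        ys = np.concatenate([ys1, ys2], axis=1)

    ys = np.clip(ys, 0.0, None)
    metadata = {
        "medium": system.medium,
        "pH": system.pH_label,
        "LH0": system.LH0,
        "R_i": system.R_i,
        "k_p": params.k_p,
        "include_initiator_O2": params.include_initiator_O2,
        "compounds": ",".join(f"{a.name}:{a.conc0:g}"
                              for a in system.antioxidants),
    }
    trace = Trace(times=times, o2_consumed=ys[_UPTAKE],
                  injection_time=t_inj, metadata=metadata)
    if not return_ledger:
        return trace
    species = pd.DataFrame(ys.T, index=pd.Index(times, name="time_s"),
                           columns=net.species_names)
    return SimulationResult(trace=trace, species=species)


def steady_state_rox(system: ExperimentSystem,
                     params: ReactionParameters) -> float:
    """Closed-form uninhibited oxidation rate k_p [LH]0 sqrt(R_i / 2k_t).

    The steady-state limit of the chain mechanism without inhibitors; used
    as the internal oracle for the simulator.
    """
    if params.two_kt <= 0:
        raise OracleUndefinedError("steady-state rate undefined for 2k_t <= 0")
    return params.k_p * system.LH0 * np.sqrt(system.R_i / params.two_kt)


def inhibited_rate_oracle(system: ExperimentSystem, params: ReactionParameters,
                          antioxidant_name: str,
                          conc: float | None = None) -> float:
    """Closed-form inhibited rate k_p [LH] R_i / (2 k_inh [ArOH]).

    Valid for a single strong, non-dimerizing antioxidant early in the
    induction period (stoichiometric factor 2).
    """
    ax = system.antioxidant(antioxidant_name)
    c = ax.conc0 if conc is None else conc
    return params.k_p * system.LH0 * system.R_i / (2.0 * ax.k_inh * c)


def closed_form_uptake(t, tau: float, k_inh: float, k_p: float, LH: float):
    """Integrated-rate oxygen uptake during the induction period.

    Delta[O2](t) = -(k_p [LH] / k_inh) ln(1 - t/tau) for 0 <= t < tau:
    the classical inhibited-autoxidation form in which the antioxidant is
    consumed linearly at R_i/n and the uptake rate is inversely
    proportional to the antioxidant remaining.  Also the model inverted by
    :func:`autoxkin.analysis.estimate_kinh`.
    """
    t = np.asarray(t, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if k_inh <= 0:
        raise ValueError("k_inh must be > 0")
    if np.any(t < 0) or np.any(t >= tau):
        raise ValueError("closed-form uptake requires 0 <= t < tau")
    out = -(k_p * LH / k_inh) * np.log1p(-t / tau)
    return float(out) if out.ndim == 0 else out


def effective_stoichiometry(system: ExperimentSystem,
                            params: ReactionParameters,
                            antioxidant_name: str,
                            t_end: float | None = None,
                            dt_out: float | None = None,
                            n_boot: int = 0) -> float:
    """Stoichiometric factor realized by the simulator for one antioxidant.

    Simulates the (single-antioxidant) system, locates the induction-period
    breakpoint and returns n_eff = R_i * tau / [ArOH]0.  Without
    dimerization the two-radical trap mechanism gives n_eff ~ 2; with
    trapping-competent dimers n_eff exceeds 2 and grows with the coupling
    cascade depth.

    Raises
    ------
    NoBreakpointError
        If the simulated trace has no detectable induction period.
    """
    from .analysis import estimate_tau   # deferred: analysis is layered above

    if len(system.antioxidants) != 1:
        raise ValueError("effective_stoichiometry requires a single "
                         "test antioxidant")
    ax = system.antioxidant(antioxidant_name)
    if system.R_i <= 0 or ax.conc0 <= 0:
        raise ValueError("R_i and conc0 must be > 0")
    depth = ax.cascade_depth if ax.dimerizes else 0
    tau_guess = (2.0 + depth) * ax.conc0 / system.R_i
    if t_end is None:
        t_end = 2.2 * tau_guess
    if dt_out is None:
        dt_out = max(tau_guess / 400.0, 0.5)
    trace = simulate(system, params, t_end=t_end, dt_out=dt_out)
    tau, _ = estimate_tau(trace, n_boot=n_boot)
    return system.R_i * tau / ax.conc0
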