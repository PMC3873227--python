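"""Config-driven parametric experiments over the convergent circuit.

Each experiment id reproduces one of the reference parametric sweeps
(convergence size, synaptic weight, retinal synchronization/jitter,
bombardment statistics, cross-cell correlation, hybrid replay, cellular
heterogeneity, coherent oscillations, and the supplementary controls) at a
configurable scale. `scale` shortens simulated durations and repetition
counts only -- model equations and analysis settings are never touched by
it. All randomness derives deterministically from the base seed via
SeedSequence spawning, so a (spec, seed) pair reproduces its table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cell_models as cm
from . import circuit_sim as cs
from . import cortical_noise as cn
from . import hybrid_replay as hr
from . import info_metrics as im
from . import stimuli as st

__all__ = ["ExperimentSpec", "run_experiment", "find_optimum", "EXPERIMENTS"]

BASE_DURATION = 100_000.0   # ms
DT = 0.025                  # ms


@dataclass(frozen=True)
class ExperimentSpec:
    """One parametric experiment: id, scale, seed and optional overrides."""

    experiment: str
    scale: float = 1.0
    seed: int = 0
    repetitions: int | None = None   # default: 10 at scale 1, else 3
    duration: float | None = None    # ms; default BASE_DURATION * scale
    dt: float = DT
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0, 1]")

    @property
    def reps(self) -> int:
        if self.repetitions is not None:
            return self.repetitions
        return 10 if self.scale >= 1.0 else 3

    @property
    def dur(self) -> float:
        return self.duration if self.duration is not None \
            else BASE_DURATION * self.scale


def _rng_for(spec: ExperimentSpec, *key) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, *map(int, key)]))


def _seed_for(spec: ExperimentSpec, *key) -> int:
    return int(_rng_for(spec, *key).integers(0, 2**31 - 1))


def _retina(spec: ExperimentSpec, rep: int) -> st.SpikeTrain:
    return st.gamma_spike_train(
        st.RetinalGenSpec(duration=spec.dur), _rng_for(spec, 9000, rep))


def _te(s: st.SpikeTrain, r: st.SpikeTrain, seed: int,
        settings: im.MISettings = im.MISettings()) -> float:
    return im.mutual_information(s, r, settings, np.random.default_rng(seed),
                                 extrapolate=True).te


def _sim_te(spec: ExperimentSpec, rep: int, circuit, trains, noise, corr,
            reference: st.SpikeTrain, currents=None, **simkw) -> dict:
    res = cs.simulate(circuit, trains, noise=noise, corr=corr,
                      currents=currents, duration=spec.dur, dt=spec.dt,
                      seed=_seed_for(spec, 1, rep), **simkw)
    te = _te(reference, res.ctx_spikes, _seed_for(spec, 2, rep))
    tc_rate = float(np.mean([t.rate for t in res.tc_spikes])) \
        if res.tc_spikes else 0.0
    return dict(te=te, tc_rate=tc_rate, ctx_rate=res.ctx_spikes.rate,
                _result=res)


# ---------------------------------------------------------------------------
# experiment implementations (each returns a list of row dicts)
# ---------------------------------------------------------------------------

def _exp_convergence_size(spec: ExperimentSpec):
    """TE vs thalamic population size for fixed TC weights + matched N*w."""
    sizes = spec.overrides.get("sizes", (10, 30, 60, 90, 120, 180, 240))
    weights = spec.overrides.get("weights", (2.33, 7.0, 21.0, None))
    rows = []
    for w in weights:
        for n in sizes:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                circ = cs.build_circuit("single", n,
                                        w_tc=w if w is not None
                                        else 210.0 / n)
                out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(),
                              cn.CorrelationSpec(), ret)
                rows.append(dict(weight=w if w is not None else -1.0,
                                 n_tc=n, repeat=rep,
                                 te=out["te"], tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_synaptic_weight(spec: ExperimentSpec):
    """TE vs TC AMPA weight for fixed population sizes."""
    sizes = spec.overrides.get("sizes", (10, 30, 90))
    weights = spec.overrides.get("weights",
                                 (0.5, 1.0, 2.33, 4.0, 7.0, 12.0, 21.0, 40.0))
    rows = []
    for n in sizes:
        for w in weights:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                circ = cs.build_circuit("single", n, w_tc=w)
                out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(),
                              cn.CorrelationSpec(), ret)
                rows.append(dict(n_tc=n, weight=w, repeat=rep, te=out["te"],
                                 tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_retinal_synchronization(spec: ExperimentSpec):
    """TE vs retinal synchronization and per-contact spike-time jitter."""
    s_grid = spec.overrides.get("s_ret", (0.0, 0.5, 1.0))
    j_grid = spec.overrides.get("jitter", (0.0, 1.0, 3.0, 10.0))
    rows = []
    for s_ret in s_grid:
        for j in j_grid:
            for rep in range(spec.reps):
                rng = _rng_for(spec, 9000, rep)
                lines = st.synchronize_lines(
                    15, s_ret, st.RetinalGenSpec(duration=spec.dur), rng)
                circ = cs.build_circuit("mixed", 30)
                circ2, trains = cs.jitter_retinal_contacts(
                    circ, lines, j, _rng_for(spec, 9100, rep))
                out = _sim_te(spec, rep, circ2, trains, cn.lc_optimal(),
                              cn.CorrelationSpec(), lines[0])
                rows.append(dict(s_ret=s_ret, jitter=j, repeat=rep,
                                 te=out["te"], tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_thalamic_jitter(spec: ExperimentSpec):
    """TE vs thalamocortical spike-time jitter."""
    j_grid = spec.overrides.get("jitter", (0.0, 1.0, 3.0, 10.0))
    rows = []
    for j in j_grid:
        for rep in range(spec.reps):
            ret = _retina(spec, rep)
            circ = cs.build_circuit("single", 30)
            out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(),
                          cn.CorrelationSpec(), ret, thalamic_jitter=j)
            rows.append(dict(jitter=j, repeat=rep, te=out["te"],
                             tc_rate=out["tc_rate"],
                             ctx_rate=out["ctx_rate"]))
    return rows


def _exp_bombardment_amplitude(spec: ExperimentSpec):
    """TE over the (a_exc, a_inh) conductance-amplitude plane (v = 0.2)."""
    a_e = spec.overrides.get("a_exc", (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0))
    a_i = spec.overrides.get("a_inh", (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0))
    rows = []
    for ae in a_e:
        for ai in a_i:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                noise = cn.OUSpec(a_exc=ae, a_inh=ai, v_exc=0.2, v_inh=0.2)
                circ = cs.build_circuit("single", 30)
                out = _sim_te(spec, rep, circ, [ret], noise,
                              cn.CorrelationSpec(), ret)
                rows.append(dict(a_exc=ae, a_inh=ai, repeat=rep, te=out["te"],
                                 tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_bombardment_fluctuation(spec: ExperimentSpec):
    """TE over the (v_exc, v_inh) variation-ratio plane at the LC point."""
    v_e = spec.overrides.get("v_exc", (0.0, 0.1, 0.2, 0.4, 0.7, 1.0))
    v_i = spec.overrides.get("v_inh", (0.0, 0.2, 0.6, 1.0))
    rows = []
    for ve in v_e:
        for vi in v_i:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                noise = cn.OUSpec(a_exc=1.5, a_inh=1.0, v_exc=ve, v_inh=vi)
                circ = cs.build_circuit("single", 30)
                out = _sim_te(spec, rep, circ, [ret], noise,
                              cn.CorrelationSpec(), ret)
                rows.append(dict(v_exc=ve, v_inh=vi, repeat=rep, te=out["te"],
                                 tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_impaired_layer(spec: ExperimentSpec):
    """Normal vs impaired (half the cells lose retinal input) layers."""
    a_e = spec.overrides.get("a_exc", (0.5, 1.0, 1.5, 2.0, 2.5))
    a_i = spec.overrides.get("a_inh", (0.5, 1.0, 1.5, 2.0))
    n = spec.overrides.get("n_tc", 90)
    rows = []
    mask = np.ones(n, dtype=bool)
    mask[n // 2:] = False
    for impaired in (False, True):
        for ae in a_e:
            for ai in a_i:
                for rep in range(spec.reps):
                    ret = _retina(spec, rep)
                    noise = cn.OUSpec(a_exc=ae, a_inh=ai, v_exc=0.2, v_inh=0.2)
                    circ = cs.build_circuit("single", n, w_tc=2.33)
                    out = _sim_te(spec, rep, circ, [ret], noise,
                                  cn.CorrelationSpec(), ret,
                                  active_mask=mask if impaired else None)
                    rows.append(dict(impaired=impaired, a_exc=ae, a_inh=ai,
                                     repeat=rep, te=out["te"],
                                     tc_rate=out["tc_rate"],
                                     ctx_rate=out["ctx_rate"]))
    return rows


def _exp_population_correlation(spec: ExperimentSpec):
    """TE, rates, CV, pairwise correlation and partial TEs vs c_pop."""
    c_grid = spec.overrides.get("c_pop", (0.0, 0.2, 0.4, 0.6, 0.8, 1.0))
    schemas = spec.overrides.get("schemas", ("homogeneous", "heterogeneous"))
    rows = []
    for schema in schemas:
        for c in c_grid:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                circ = cs.build_circuit("single", 30)
                corr = cn.CorrelationSpec(c_pop=c, schema=schema)
                out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(), corr, ret)
                res = out.pop("_result")
                mean_rho, _ = im.population_pairwise_correlation(
                    res.tc_spikes[::max(1, len(res.tc_spikes) // 10)])
                rt, tc, _ = im.partial_te(
                    ret, res.tc_spikes[0], res.ctx_spikes,
                    rng=np.random.default_rng(_seed_for(spec, 3, rep)))
                _, cv = im.rate_and_cv(res.tc_spikes[0])
                rows.append(dict(schema=schema, c_pop=c, repeat=rep,
                                 te=out["te"], tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"],
                                 pair_rho=mean_rho, tc_cv=cv,
                                 te_retinothalamic=rt.te,
                                 te_thalamocortical=tc.te))
    return rows


def _exp_hybrid_replay(spec: ExperimentSpec):
    """Synthetic hybrid-replay layers: TE vs correlation and layer size."""
    n_sets = spec.overrides.get("n_sets", max(2, int(round(15 * spec.scale))))
    n_common_grid = spec.overrides.get("n_common", (1, 4, 7, 10))
    dur = spec.overrides.get("replay_duration", min(spec.dur, 40_000.0))
    rng = _rng_for(spec, 5000)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=dur), rng)
    sets = hr.generate_pseudo_recordings(
        ret, cn.lc_optimal(), n_cells=n_sets, duration=dur, rng=rng)
    settings = im.MISettings(bin_size=3.0)
    rows = []
    for i, sset in enumerate(sets):
        for m in n_common_grid:
            layer = hr.assemble_layer(
                hr.HybridLayerSpec("small_single", n_common=m), [sset], rng)
            res = hr.replay(layer, w_tc=cs.tc_weight_for(10))
            te = im.mutual_information(
                ret, res.ctx_spikes, settings,
                np.random.default_rng(_seed_for(spec, 6, i, m)),
                extrapolate=True).te
            rows.append(dict(kind="small_single", set_id=i, n_common=m,
                             c_pop=(m - 1) / 9.0, n=10, te=te,
                             ctx_rate=res.ctx_spikes.rate))
    sizes = spec.overrides.get("sizes", (10, 50, 90, 130))
    for kind in ("large_mixed", "large_single"):
        for cond in ("correlated", "decorrelated"):
            for n in sizes:
                try:
                    layer = hr.assemble_layer(
                        hr.HybridLayerSpec(kind, n=n, condition=cond),
                        sets, rng)
                except ValueError:
                    continue
                res = hr.replay(layer, w_tc=2.33)
                te = im.mutual_information(
                    ret, res.ctx_spikes, settings,
                    np.random.default_rng(_seed_for(spec, 7, n)),
                    extrapolate=True).te
                rows.append(dict(kind=kind, set_id=-1, n_common=-1,
                                 c_pop=np.nan, n=n, condition=cond, te=te,
                                 ctx_rate=res.ctx_spikes.rate))
    return rows


def _exp_cellular_heterogeneity(spec: ExperimentSpec):
    """TE vs cellular heterogeneity, correlated and uncorrelated noise."""
    h_grid = spec.overrides.get("h", (0.0, 0.2, 0.4, 0.6, 0.8, 1.0))
    rows = []
    for c_pop in (0.0, 1.0):
        for h in h_grid:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                circ = cs.build_circuit("single", 30, heterogeneity=h,
                                        rng=_rng_for(spec, 9200, rep))
                out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(),
                              cn.CorrelationSpec(c_pop=c_pop), ret)
                rows.append(dict(c_pop=c_pop, heterogeneity=h, repeat=rep,
                                 te=out["te"], tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_thalamic_oscillations(spec: ExperimentSpec):
    """Coherent vs desynchronized sine currents in the thalamic layer."""
    amps = spec.overrides.get("amps", (0.0, 0.1, 0.2, 0.4, 0.6))
    freqs = spec.overrides.get("freqs", (5.0, 10.0, 30.0, 60.0))
    rows = []
    for coherent in (True, False):
        for f in freqs:
            for a in amps:
                for rep in range(spec.reps):
                    ret = _retina(spec, rep)
                    circ = cs.build_circuit("single", 30)
                    prng = _rng_for(spec, 9300, rep)
                    if coherent:
                        currents = st.CurrentSpec(sine_amp=a, sine_freq=f)
                    else:
                        currents = [st.CurrentSpec(
                            sine_amp=a, sine_freq=f,
                            phase=float(prng.uniform(0, 2 * np.pi)))
                            for _ in range(30)]
                    out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(),
                                  cn.CorrelationSpec(), ret,
                                  currents=currents)
                    rows.append(dict(coherent=coherent, freq=f, amp=a,
                                     repeat=rep, te=out["te"],
                                     tc_rate=out["tc_rate"],
                                     ctx_rate=out["ctx_rate"]))
    return rows


def _exp_event_threshold(spec: ExperimentSpec):
    """Single-event AMPA transfer functions of both model cells."""
    amps = spec.overrides.get("amps",
                              (5, 10, 20, 30, 40, 60, 80, 100, 120, 160))
    rows = []
    for cell in ("ctx", "tc"):
        params = cm.ctx_default() if cell == "ctx" else cm.tc_default()
        v_rest, _ = cm.rest_properties(params)
        for a in amps:
            p_spike = _event_spike_probability(params, v_rest, a, spec.dt)
            rows.append(dict(cell=cell, amp=float(a), p_spike=p_spike))
    return rows


def _event_spike_probability(params, v0, w, dt, n_events: int = 1) -> float:
    """Deterministic no-noise case: probability is 0 or 1."""
    par = cm.params_to_vector(params)
    step = np.array([int(50.0 / dt)], dtype=np.int64)
    _, sp, nsp = cm.K.simulate_cell(
        par, dt, int(120.0 / dt), v0,
        step, np.array([float(w)]), 1.0, 0.0,
        np.empty(0, dtype=np.int64), np.empty(0), 2.0, -75.0,
        np.empty(0), np.empty(0), 0.0, -75.0,
        0.0, 0.0, 0.0, 0.0, 16)
    return float(nsp >= 1)


def _exp_depolarization(spec: ExperimentSpec):
    """Depolarizing constant current vs bombardment amplitude."""
    i_grid = spec.overrides.get("i_const", (0.0, 0.3, 0.6))
    a_grid = spec.overrides.get("a_exc", (0.0, 0.5, 1.0, 1.5, 2.0))
    rows = []
    for i0 in i_grid:
        for ae in a_grid:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                noise = cn.OUSpec(a_exc=ae, a_inh=ae / 1.5, v_exc=0.2,
                                  v_inh=0.2)
                circ = cs.build_circuit("single", 30)
                out = _sim_te(spec, rep, circ, [ret], noise,
                              cn.CorrelationSpec(), ret,
                              currents=st.CurrentSpec(i_const=i0))
                rows.append(dict(i_const=i0, a_exc=ae, repeat=rep,
                                 te=out["te"], tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


def _exp_feedforward_inhibition(spec: ExperimentSpec):
    """Feedforward inhibition weight x lag, optimal and saturated regimes."""
    w_grid = spec.overrides.get("w_gaba", (0.0, 1.0, 3.0, 5.0, 8.0))
    lag_grid = spec.overrides.get("lags", (0.0, 1.0, 3.0))
    regimes = dict(lc=cn.lc_optimal(),
                   saturated=cn.OUSpec(a_exc=3.0, a_inh=0.5, v_exc=0.2,
                                       v_inh=0.2))
    rows = []
    for regime, noise in regimes.items():
        for w in w_grid:
            for lag in lag_grid:
                for rep in range(spec.reps):
                    ret = _retina(spec, rep)
                    circ = cs.build_circuit("single", 30)
                    if w > 0:
                        circ = cs.attach_ffi(circ, w, lag)
                    out = _sim_te(spec, rep, circ, [ret], noise,
                                  cn.CorrelationSpec(), ret)
                    rows.append(dict(regime=regime, w_gaba=w, lag=lag,
                                     repeat=rep, te=out["te"],
                                     tc_rate=out["tc_rate"],
                                     ctx_rate=out["ctx_rate"]))
    return rows


def _exp_exc_inh_correlation(spec: ExperimentSpec):
    """Exc-inh correlation strength x lag at the single-cell level."""
    c_grid = spec.overrides.get("c_ei", (0.0, 0.5, 1.0))
    lag_grid = spec.overrides.get("lags", (0.0, 2.0, 5.0, 10.0))
    rows = []
    for c in c_grid:
        for lag in lag_grid:
            for rep in range(spec.reps):
                ret = _retina(spec, rep)
                circ = cs.build_circuit("single", 30)
                corr = cn.CorrelationSpec(c_ei=c, lag_ei=lag)
                out = _sim_te(spec, rep, circ, [ret], cn.lc_optimal(),
                              corr, ret)
                rows.append(dict(c_ei=c, lag_ei=lag, repeat=rep,
                                 te=out["te"], tc_rate=out["tc_rate"],
                                 ctx_rate=out["ctx_rate"]))
    return rows


EXPERIMENTS = {
    "convergence_size": _exp_convergence_size,
    "synaptic_weight": _exp_synaptic_weight,
    "retinal_synchronization": _exp_retinal_synchronization,
    "thalamic_jitter": _exp_thalamic_jitter,
    "bombardment_amplitude": _exp_bombardment_amplitude,
    "bombardment_fluctuation": _exp_bombardment_fluctuation,
    "impaired_layer": _exp_impaired_layer,
    "population_correlation": _exp_population_correlation,
    "hybrid_replay": _exp_hybrid_replay,
    "cellular_heterogeneity": _exp_cellular_heterogeneity,
    "thalamic_oscillations": _exp_thalamic_oscillations,
    "event_threshold": _exp_event_threshold,
    "depolarization": _exp_depolarization,
    "feedforward_inhibition": _exp_feedforward_inhibition,
    "exc_inh_correlation": _exp_exc_inh_correlation,
}


def run_experiment(spec: ExperimentSpec, out_path=None,
                   log=None) -> pd.DataFrame:
    """Execute one experiment and return its long-format result table."""
    if spec.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {spec.experiment!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    rows = EXPERIMENTS[spec.experiment](spec)
    df = pd.DataFrame(rows)
    df.insert(0, "experiment", spec.experiment)
    df["scale"] = spec.scale
    df["base_seed"] = spec.seed
    if out_path is not None:
        df.to_csv(out_path, index=False)
    if log is not None:
        log(f"{spec.experiment}: {len(df)} rows")
    return df


def find_optimum(table: pd.DataFrame, metric: str = "te",
                 by: str | list[str] | None = None,
                 smoothing: bool = False) -> tuple[dict, float]:
    """Grid point maximizing the repeat-averaged metric.

    Ties break toward the smaller parameter value; optional 3-point moving
    average for noisy 1-D sweeps.
    """
    if table.empty:
        raise ValueError("empty sweep table")
    drop = {"experiment", "repeat", "scale", "base_seed", metric}
    group_cols = [c for c in table.columns if c not in drop
                  and not c.startswith("te") and not c.endswith("rate")
                  and c != "pair_rho"] if by is None else \
        ([by] if isinstance(by, str) else list(by))
    agg = table.groupby(group_cols, as_index=False)[metric].mean()
    if agg[metric].isna().all():
        raise ValueError("metric is all-NaN")
    agg = agg.sort_values(group_cols).reset_index(drop=True)
    vals = agg[metric].to_numpy()
    if smoothing and len(vals) >= 3:
        sm = vals.copy()
        sm[1:-1] = (vals[:-2] + vals[1:-1] + vals[2:]) / 3.0
        vals = sm
    best = int(np.nanargmax(vals))   # argmax takes the first (smallest) tie
    point = agg.iloc[best][group_cols].to_dict()
    return point, float(vals[best])
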