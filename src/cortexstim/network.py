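"""Hodgkin-Huxley point-neuron model of a canonical cortical column.

Membrane dynamics (per neuron i):

    C_m dV/dt = I_ion(V) + I_syn + I_ext + eta * xi(t)

    I_ion = g_Na m^3 h (V_Na - V) + g_K n^4 (V_K - V) + g_L (V_L - V)
          + g_Ca (V_Ca - V) / (1 + exp(-(V - V_th)/V_shp))
          + g_ahp c/(c + k_d) (V_K - V)

with Traub-Miles style gating kinetics (rate functions below), a
high-threshold calcium current and a calcium-gated AHP potassium current
that produces spike-frequency adaptation in regular-spiking (RS) cells.
Fast-spiking (FS) cells have g_Ca = g_ahp = 0 and do not adapt.  Calcium
follows

    dc/dt = -alpha_Ca g_Ca (V - V_Ca) / (1 + exp(-(V - V_th)/V_shp)) - c/tau_Ca

Synapses are conductance-based first-order kinetic (AMPA / GABA_A):

    I_syn_i = sum_j G_ij^exc s_j (V_exc - V_i) + sum_j G_ij^inh s_j (V_inh - V_i)
    ds_j/dt = alpha_s S(V_j) (1 - s_j) - beta_s s_j,
    S(V) = 1 / (1 + exp(-100 (V - 20)))

The column holds three layers (II/III, IV, V), each with excitatory cells
(pyramidal / spiny stellate, RS), basket cells (FS) and Martinotti cells
(RS with low leak), wired as a canonical microcircuit: recurrent excitation
within each layer, strong ascending drive from layer IV and Va excitatory
cells to layer II/III, lateral basket inhibition within each layer, and
Martinotti cross-layer inhibition onto layer IV (from MC5) and onto layers
IV and II/III (from MC4).  Stimulation enters as a brief per-cell current
pulse during the seeding window, calibrated so each population fires with
the probability estimated by the activating-function analysis.

Units: mV, ms, μF/cm², mS/cm², μA/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Single-cell parameters (μF/cm², mS/cm², mV, ms)."""

    cm: float = 1.0
    g_na: float = 100.0
    g_k: float = 80.0
    g_l: float = 0.1
    g_ca: float = 0.0
    g_ahp: float = 0.0
    v_na: float = 50.0
    v_k: float = -100.0
    v_l: float = -67.0
    v_ca: float = 120.0
    v_th: float = -25.0      # calcium-current sigmoid midpoint
    v_shp: float = 5.0       # calcium-current sigmoid slope
    k_d: float = 5.0
    alpha_ca: float = 0.0005
    tau_ca: float = 300.0
    cell_class: str = "RS"

    def __post_init__(self) -> None:
        if self.cell_class not in ("RS", "FS"):
            raise ValueError("cell_class must be 'RS' or 'FS'")
        if self.cell_class == "FS" and (self.g_ca != 0 or self.g_ahp != 0):
            raise ValueError("FS cells must have g_ca = g_ahp = 0")


#: Regular-spiking excitatory cell (adapting).
RS_PARAMS = NeuronParams(g_l=0.15, g_ca=1.0, g_ahp=1.0, cell_class="RS")
#: Fast-spiking basket interneuron: no adaptation, lower leak (more excitable).
FS_PARAMS = NeuronParams(g_l=0.08, cell_class="FS")
#: Martinotti interneuron: regular spiking but interneuron-like low leak.
MC_PARAMS = replace(RS_PARAMS, g_l=0.08)


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic synapse constants per receptor class (1/ms, mV)."""

    alpha_exc: float = 1.1
    beta_exc: float = 0.5
    alpha_inh: float = 1.0
    beta_inh: float = 0.1
    v_syn_exc: float = 0.0
    v_syn_inh: float = -80.0


@dataclass(frozen=True)
class Population:
    name: str
    layer: str
    size: int
    params: NeuronParams
    excitatory: bool


@dataclass(frozen=True)
class Connection:
    """One allowed projection of the canonical circuit."""

    pre: str
    post: str
    probability: float
    weight: float        # total synaptic conductance budget, mS/cm²; the
                         # per-synapse conductance is weight / expected indegree

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("connection probability must be in [0, 1]")
        if self.weight < 0:
            raise ValueError("connection weight must be non-negative")


@dataclass
class ColumnConfig:
    """Populations + connectivity of the reduced canonical column."""

    populations: list[Population]
    connections: list[Connection]
    synapses: SynapseParams = field(default_factory=SynapseParams)
    noise_eta: float = 0.0           # white-noise sd, μA/cm²
    dt_ms: float = 0.025
    seed: int = 0

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"unknown population {name!r}")


def default_column(exc_size: int = 60, bc_size: int = 20, mc_size: int = 10,
                   noise_eta: float = 0.0, seed: int = 0) -> ColumnConfig:
    """Reduced canonical column: 3 layers x (exc, BC, MC).

    Weights are total conductance budgets normalized by expected indegree at
    wiring time, so behavior is robust to population size.  Basket inhibition
    is strong and somatic-like (it can veto marginally seeded excitatory
    spikes); Martinotti inhibition is weak and distal-like (a background
    brake that does not silence the column on its own).
    """
    pops = []
    for layer, tag in (("II/III", "23"), ("IV", "4"), ("V", "5")):
        pops += [
            Population(f"exc{tag}", layer, exc_size, RS_PARAMS, True),
            Population(f"BC{tag}", layer, bc_size, FS_PARAMS, False),
            Population(f"MC{tag}", layer, mc_size, MC_PARAMS, False),
        ]
    conns = []
    for tag in ("23", "4", "5"):
        conns += [
            Connection(f"exc{tag}", f"exc{tag}", 0.2, 0.50),   # recurrent
            Connection(f"exc{tag}", f"BC{tag}", 0.3, 0.10),
            Connection(f"exc{tag}", f"MC{tag}", 0.3, 0.07),
            Connection(f"BC{tag}", f"exc{tag}", 0.5, 2.00),    # lateral inhibition
        ]
    conns += [
        Connection("exc4", "exc23", 0.3, 0.35),    # ascending canonical drive
        Connection("exc5", "exc23", 0.3, 0.28),    # layer Va -> II/III
        Connection("exc4", "exc5", 0.2, 0.15),     # moderate IV -> Va
        Connection("MC4", "exc4", 0.3, 0.20),      # Martinotti cross-layer
        Connection("MC4", "exc23", 0.3, 0.20),
        Connection("MC5", "exc4", 0.3, 0.20),
    ]
    return ColumnConfig(pops, conns, noise_eta=noise_eta, seed=seed)


# ---------------------------------------------------------------------------
# Gating kinetics (rate constants in 1/ms, V in mV)
# ---------------------------------------------------------------------------

def _safe_ratio(num: np.ndarray, den: np.ndarray, limit: float) -> np.ndarray:
    """num/den with the removable singularity at den == 0 replaced by limit."""
    num, den = np.asarray(num, float), np.asarray(den, float)
    tiny = np.abs(den) < 1e-9
    den = np.where(tiny, 1.0, den)
    return np.where(tiny, limit, num / den)


def alpha_m(v):
    return _safe_ratio(0.32 * (v + 54.0), 1.0 - np.exp(-0.25 * (v + 54.0)), 1.28)


def beta_m(v):
    return _safe_ratio(0.28 * (v + 27.0), np.exp(0.2 * (v + 27.0)) - 1.0, 1.4)


def alpha_h(v):
    return 0.128 * np.exp(-(50.0 + v) / 18.0)


def beta_h(v):
    return 4.0 / (1.0 + np.exp(-0.2 * (v + 27.0)))


def alpha_n(v):
    return _safe_ratio(0.032 * (v + 52.0), 1.0 - np.exp(-0.2 * (v + 52.0)), 0.16)


def beta_n(v):
    return 0.5 * np.exp(-(57.0 + v) / 40.0)


def s_gate(v):
    """Presynaptic transmitter-release sigmoid S(V)."""
    return 1.0 / (1.0 + np.exp(np.clip(-100.0 * (v - 20.0), -500.0, 500.0)))


def steady_state(v: float) -> tuple[float, float, float]:
    """(m_inf, h_inf, n_inf) at a holding voltage."""
    am, bm = alpha_m(v), beta_m(v)
    ah, bh = alpha_h(v), beta_h(v)
    an, bn = alpha_n(v), beta_n(v)
    return (float(am / (am + bm)), float(ah / (ah + bh)), float(an / (an + bn)))


# ---------------------------------------------------------------------------
# Network state and integration
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A realized column: vectorized parameter arrays and weight matrices."""

    config: ColumnConfig
    pop_slices: dict[str, slice]
    pop_of: np.ndarray               # per-neuron population index
    pop_names: list[str]
    excitatory: np.ndarray           # per-neuron bool
    w_exc: np.ndarray                # (n, n) conductance, post x pre
    w_inh: np.ndarray
    # per-neuron parameter arrays
    cm: np.ndarray
    g_na: np.ndarray
    g_k: np.ndarray
    g_l: np.ndarray
    g_ca: np.ndarray
    g_ahp: np.ndarray
    v_na: np.ndarray
    v_k: np.ndarray
    v_l: np.ndarray
    v_ca: np.ndarray
    v_th: np.ndarray
    v_shp: np.ndarray
    k_d: np.ndarray
    alpha_ca: np.ndarray
    tau_ca: np.ndarray

    @property
    def n(self) -> int:
        return len(self.pop_of)


def build_column(config: ColumnConfig,
                 seed: int | None = None) -> Network:
    """Realize the synaptic graph by independent Bernoulli draws per edge.

    Only the listed canonical projections can carry synapses; all other
    population pairs stay empty.  Per-synapse conductance is the connection
    weight divided by the expected indegree ``p * n_pre`` so the total drive
    a cell receives is size-independent.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = [p.name for p in config.populations]
    sizes = [p.size for p in config.populations]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    pop_slices = {nm: slice(int(offsets[i]), int(offsets[i + 1]))
                  for i, nm in enumerate(names)}
    pop_of = np.concatenate([np.full(sz, i) for i, sz in enumerate(sizes)])
    excitatory = np.concatenate(
        [np.full(p.size, p.excitatory) for p in config.populations])

    def arr(attr):
        return np.concatenate([np.full(p.size, getattr(p.params, attr))
                               for p in config.populations])

    w_exc = np.zeros((n, n))
    w_inh = np.zeros((n, n))
    for c in config.connections:
        pre_pop = config.population(c.pre)
        s_pre, s_post = pop_slices[c.pre], pop_slices[c.post]
        n_pre = pre_pop.size
        expected_indegree = max(c.probability * n_pre, 1.0)
        g = c.weight / expected_indegree
        mask = rng.random((s_post.stop - s_post.start, n_pre)) < c.probability
        target = w_exc if pre_pop.excitatory else w_inh
        target[s_post, s_pre] += g * mask
    return Network(
        config=config, pop_slices=pop_slices, pop_of=pop_of,
        pop_names=names, excitatory=excitatory, w_exc=w_exc, w_inh=w_inh,
        cm=arr("cm"), g_na=arr("g_na"), g_k=arr("g_k"), g_l=arr("g_l"),
        g_ca=arr("g_ca"), g_ahp=arr("g_ahp"), v_na=arr("v_na"),
        v_k=arr("v_k"), v_l=arr("v_l"), v_ca=arr("v_ca"), v_th=arr("v_th"),
        v_shp=arr("v_shp"), k_d=arr("k_d"), alpha_ca=arr("alpha_ca"),
        tau_ca=arr("tau_ca"))


@dataclass
class SpikeRaster:
    """Spike times (ms) with cell ids and population labels."""

    times_ms: np.ndarray
    cell_ids: np.ndarray
    populations: np.ndarray          # per-spike population name

    def __len__(self) -> int:
        return len(self.times_ms)

    def population_response(self, population: str, pop_size: int,
                            t_start: float = 0.0,
                            t_stop: float = np.inf) -> float:
        """Spikes per cell in the population over [t_start, t_stop)."""
        sel = (self.populations == population) \
            & (self.times_ms >= t_start) & (self.times_ms < t_stop)
        return float(sel.sum()) / pop_size


class _State:
    """Vectorized integrator state for one column."""

    def __init__(self, net: Network):
        n = net.n
        v0 = -67.0
        m0, h0, n0 = steady_state(v0)
        self.v = np.full(n, v0)
        self.m = np.full(n, m0)
        self.h = np.full(n, h0)
        self.n = np.full(n, n0)
        self.c = np.zeros(n)
        self.s_exc = np.zeros(n)
        self.s_inh = np.zeros(n)


def _derivs(net: Network, st: _State, i_ext: np.ndarray,
            syn: SynapseParams):
    """Time derivatives of (v, m, h, n, c, s_exc, s_inh)."""
    v = st.v
    ca_gate = 1.0 / (1.0 + np.exp(-(v - net.v_th) / net.v_shp))
    i_ion = (net.g_na * st.m ** 3 * st.h * (net.v_na - v)
             + net.g_k * st.n ** 4 * (net.v_k - v)
             + net.g_l * (net.v_l - v)
             + net.g_ca * ca_gate * (net.v_ca - v)
             + net.g_ahp * st.c / (st.c + net.k_d) * (net.v_k - v))
    g_e = net.w_exc @ st.s_exc
    g_i = net.w_inh @ st.s_inh
    i_syn = g_e * (syn.v_syn_exc - v) + g_i * (syn.v_syn_inh - v)
    dv = (i_ion + i_syn + i_ext) / net.cm
    dm = alpha_m(v) * (1.0 - st.m) - beta_m(v) * st.m
    dh = alpha_h(v) * (1.0 - st.h) - beta_h(v) * st.h
    dn = alpha_n(v) * (1.0 - st.n) - beta_n(v) * st.n
    dc = (-net.alpha_ca * net.g_ca * ca_gate * (v - net.v_ca)
          - st.c / net.tau_ca)
    rel = s_gate(v)
    ds_e = syn.alpha_exc * rel * (1.0 - st.s_exc) - syn.beta_exc * st.s_exc
    ds_i = syn.alpha_inh * rel * (1.0 - st.s_inh) - syn.beta_inh * st.s_inh
    return dv, dm, dh, dn, dc, ds_e, ds_i


def simulate(net: Network, i_ext_fn: Callable[[float], np.ndarray] | None,
             duration_ms: float, seed: int = 0,
             dt_ms: float | None = None,
             noise_eta: float | None = None,
             v_spike_mv: float = 0.0,
             refractory_ms: float = 2.0) -> SpikeRaster:
    """Fixed-step integration (Heun / RK2 drift, Euler-Maruyama noise).

    ``i_ext_fn(t)`` returns the per-cell external current (μA/cm²) at time t;
    None means no input.  Spikes are upward crossings of ``v_spike_mv``
    deduplicated by a refractory hold.  Reproducible for a fixed seed.
    """
    syn = net.config.synapses
    dt = net.config.dt_ms if dt_ms is None else dt_ms
    eta = net.config.noise_eta if noise_eta is None else noise_eta
    rng = np.random.default_rng(seed)
    st = _State(net)
    n_steps = int(round(duration_ms / dt))
    zero = np.zeros(net.n)
    last_spike = np.full(net.n, -np.inf)
    above = st.v >= v_spike_mv
    sp_t: list[float] = []
    sp_i: list[np.ndarray] = []
    pop_label = np.array([net.pop_names[i] for i in net.pop_of])

    fields = ("v", "m", "h", "n", "c", "s_exc", "s_inh")
    for step in range(n_steps):
        t = step * dt
        i_ext = i_ext_fn(t) if i_ext_fn is not None else zero
        k1 = _derivs(net, st, i_ext, syn)
        trial = _State.__new__(_State)
        for name, d in zip(fields, k1):
            setattr(trial, name, getattr(st, name) + dt * d)
        i_ext2 = i_ext_fn(t + dt) if i_ext_fn is not None else zero
        k2 = _derivs(net, trial, i_ext2, syn)
        for name, d1, d2 in zip(fields, k1, k2):
            setattr(st, name, getattr(st, name) + 0.5 * dt * (d1 + d2))
        if eta > 0:
            st.v = st.v + (eta * np.sqrt(dt) / net.cm) \
                * rng.standard_normal(net.n)
        if not np.all(np.isfinite(st.v)):
            bad = np.flatnonzero(~np.isfinite(st.v))[:5]
            raise FloatingPointError(
                f"integration diverged at t={t:.3f} ms, cells {bad.tolist()}")
        now_above = st.v >= v_spike_mv
        crossing = now_above & ~above & (t - last_spike >= refractory_ms)
        if crossing.any():
            idx = np.flatnonzero(crossing)
            last_spike[idx] = t
            sp_t.append(t + dt)
            sp_i.append(idx)
        above = now_above
    if sp_t:
        times = np.concatenate([np.full(len(i), tt)
                                for tt, i in zip(sp_t, sp_i)])
        ids = np.concatenate(sp_i)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(times[order], ids[order].astype(int),
                       pop_label[ids[order].astype(int)]
                       if len(ids) else np.empty(0, dtype=object))


# ---------------------------------------------------------------------------
# Single-cell helpers
# ---------------------------------------------------------------------------

def single_cell_network(params: NeuronParams,
                        dt_ms: float = 0.025) -> Network:
    """A one-neuron 'column' for current-clamp style protocols."""
    cfg = ColumnConfig([Population("cell", "-", 1, params, True)], [],
                       dt_ms=dt_ms)
    return build_column(cfg, seed=0)


def step_current(amplitude: float, t_on: float = 0.0,
                 t_off: float = np.inf, n: int = 1):
    def fn(t):
        return (np.full(n, amplitude) if t_on <= t < t_off
                else np.zeros(n))
    return fn


def isi_sequence(params: NeuronParams, amplitude: float,
                 duration_ms: float = 600.0,
                 dt_ms: float = 0.025) -> np.ndarray:
    """Inter-spike intervals of one cell under sustained current."""
    net = single_cell_network(params, dt_ms)
    raster = simulate(net, step_current(amplitude), duration_ms, seed=0)
    return np.diff(raster.times_ms)


# ---------------------------------------------------------------------------
# Stimulus seeding
# ---------------------------------------------------------------------------

@dataclass
class StimulusSeed:
    """Per-cell pulse schedule realizing target activation probabilities."""

    amplitudes: np.ndarray           # μA/cm² per cell (0 = not pulsed)
    window_ms: float
    targets: dict[str, float]

    def i_ext_fn(self) -> Callable[[float], np.ndarray]:
        amps = self.amplitudes
        zeros = np.zeros_like(amps)
        w = self.window_ms

        def fn(t):
            return amps if 0.0 <= t < w else zeros
        return fn


def calibrate_pulse(params: NeuronParams, window_ms: float = 0.2,
                    dt_ms: float = 0.025, deadline_ms: float = 2.0,
                    amp_cap: float = 20000.0) -> float:
    """Minimal pulse amplitude (bisection) firing an isolated cell.

    A current of the returned amplitude applied for ``window_ms`` elicits
    exactly one spike within ``deadline_ms``.  Raises if even ``amp_cap``
    cannot elicit a spike.
    """
    net = single_cell_network(params, dt_ms)

    def spikes(amp: float) -> int:
        r = simulate(net, step_current(amp, 0.0, window_ms),
                     deadline_ms + 2.0, seed=0)
        return int(np.sum(r.times_ms <= deadline_ms))

    lo, hi = 0.0, 256.0
    while spikes(hi) < 1:
        hi *= 2.0
        if hi > amp_cap:
            raise RuntimeError(
                f"no spike within {deadline_ms} ms at amplitude cap {amp_cap}")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def seed_stimulus(net: Network, probabilities: Mapping[str, float],
                  seed: int = 0, window_ms: float = 0.2,
                  exc_safety: float = 1.1, inh_safety: float = 2.0,
                  _pulse_cache: dict | None = None) -> StimulusSeed:
    """Draw the pulsed subset of each population and set pulse amplitudes.

    Each cell of population P is pulsed independently with probability
    ``probabilities[P]`` (default 0); pulse amplitude is the calibrated
    single-cell threshold for that cell's parameter set times a class
    margin.  Excitatory cells get a just-suprathreshold pulse (spike
    latency ~1.5-2 ms, so concurrent inhibition can still veto the spike);
    interneurons get a strong pulse (latency ~0.5 ms), reflecting the
    short-latency responses of highly excitable interneurons.
    """
    for name, p in probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {name!r} outside [0, 1]")
        net.config.population(name)   # raises on unknown population
    rng = np.random.default_rng(seed)
    amps = np.zeros(net.n)
    cache = _pulse_cache if _pulse_cache is not None else {}
    for pop in net.config.populations:
        p = float(probabilities.get(pop.name, 0.0))
        if p == 0.0:
            continue
        key = pop.params
        if key not in cache:
            cache[key] = calibrate_pulse(pop.params, window_ms,
                                         net.config.dt_ms)
        sl = net.pop_slices[pop.name]
        chosen = rng.random(pop.size) < p
        safety = exc_safety if pop.excitatory else inh_safety
        amps[sl] = np.where(chosen, safety * cache[key], 0.0)
    return StimulusSeed(amps, window_ms, dict(probabilities))


def response_vs_current(config: ColumnConfig,
                        probability_curves: Mapping[str, Callable[[float], float]],
                        i_grid: Sequence[float],
                        seeds: Sequence[int] = (0, 1, 2, 3, 4),
                        duration_ms: float = 60.0,
                        window_ms: float = 0.2,
                        response_window_ms: float = 40.0,
                        stim_draws: int = 3,
                        response_populations: Sequence[str] | None = None,
                        ) -> dict[str, np.ndarray]:
    """Population response (spikes / N) vs electrode current, per seed.

    ``probability_curves[pop](I)`` gives the seeding probability of each
    population at signed current I (from the ensemble analysis or a user
    table).  For each current and network seed the column is rebuilt
    (graph), seeded and simulated ``stim_draws`` times with independent
    stimulus draws; the per-seed response is the mean over draws of spikes
    per cell within ``response_window_ms``.  Returned arrays have shape
    (len(seeds), len(i_grid)); average over axis 0 for the mean curve.
    """
    i_grid = np.asarray(i_grid, dtype=float)
    pops = response_populations or [p.name for p in config.populations
                                    if p.excitatory]
    out = {p: np.zeros((len(seeds), len(i_grid))) for p in pops}
    cache: dict = {}
    for j, cur in enumerate(i_grid):
        targets = {name: float(np.clip(fn(float(cur)), 0.0, 1.0))
                   for name, fn in probability_curves.items()}
        for si, s in enumerate(seeds):
            net = build_column(config, seed=int(s))
            for d in range(stim_draws):
                ss = np.random.SeedSequence([int(s), j, d]).generate_state(2)
                stim = seed_stimulus(net, targets,
                                     seed=int(ss[0] % (2 ** 31)),
                                     window_ms=window_ms,
                                     _pulse_cache=cache)
                raster = simulate(net, stim.i_ext_fn(), duration_ms,
                                  seed=int(ss[1] % (2 ** 31)))
                for p in pops:
                    out[p][si, j] += raster.population_response(
                        p, config.population(p).size,
                        t_stop=response_window_ms) / stim_draws
    return out
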