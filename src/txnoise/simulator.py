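"""Exact stochastic simulation of five gene-expression networks.

Networks (all rates per unit mature-mRNA lifetime, ``deltaM = 1`` by
convention):

``M1``   constitutive maturation: nascent mRNA synthesised at ``KN``, spliced
         to mature at ``KM`` (or after a fixed/Erlang delay), mature decays
         at ``deltaM``.
``M2``   two-stage model: mRNA at ``Km``, translated at ``Kp``, decays
         ``delta_m`` / ``delta_p``.  The mRNA occupies the ``mature`` column.
``M3``   three-stage: M2 plus two-state promoter switching (on-rate ``lam``,
         off-rate ``mu``).
``M4``   four-stage: M3 plus mRNA maturation (transcription only while
         active).
``MS3``  multiscale three-state promoter: inactive S0, transcription-factor
         bound S10, polymerase-paused S11.  S0->S10 at ``lam``; S10->S0 and
         S11->S0 at ``mu``; S10->S11 at ``lam2``; transcription at ``KN``
         fires only from S11 and drops the promoter back to S10.

Snapshots are single exact-SSA realisations started from the empty, inactive
state and run past relaxation (default ``t_end = max(15, 10/deltaP)`` when
the network makes protein, else 15; the protein autocorrelation time
``1/deltaP`` dominates convergence).  Fixed and Erlang maturation delays are
handled by an event queue of scheduled completions interleaved exactly with
the SSA steps; Erlang delays are drawn as a gamma variate at scheduling time,
which is provably equivalent to chaining exponential pseudo-stages.

Populations with extrinsic noise draw one parameter vector per cell
(independently across parameters) and hold it fixed for that cell's
simulation — static extrinsic noise.  Dual-reporter mode runs two SSA
realisations per cell sharing the parameter draw, giving conditionally
independent, identically distributed reporter copies by construction.

The multiscale network optionally carries cell-cycle features: replication
doubles the gene copy number after an Erlang(12, rate) phase and scales the
activation rate by a dosage-compensation factor (0.7); division follows a
second Erlang(12, rate) phase (total cycle length Erlang(24, rate)), thins
every molecule binomially with probability 1/2 and follows one daughter.
Snapshots are taken at a uniformly random time inside a post-burn-in cycle,
emulating an unsynchronised population.  In dual-reporter mode the two
copies share the cell's replication/division schedule and snapshot time
(both reporters live in the same cell) while reaction noise and partitioning
remain independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from .distributions import ConfigurationError, NoiseSpec, ParameterError

__all__ = [
    "GeneParams",
    "ModelSpec",
    "CellCycleSpec",
    "PopulationSample",
    "ssa_snapshot",
    "simulate_population",
    "simulate_cell_cycle",
    "propensity_table",
    "canonical_param",
    "default_t_end",
]

_NETWORKS = {"M1": 1, "M2": 2, "M3": 3, "M4": 4, "MS3": 5}
_HAS_NASCENT = {"M1", "M4", "MS3"}
_HAS_PROTEIN = {"M2", "M3", "M4", "MS3"}
_CANONICAL = ("lam", "mu", "lam2", "KN", "KM", "KP", "deltaM", "deltaP")

PARAM_ALIASES = {
    "lam1": "lam", "mu1": "mu",
    "Km": "KN", "Kp": "KP",
    "delta_m": "deltaM", "delta_p": "deltaP",
    "dM": "deltaM", "dP": "deltaP",
}


def canonical_param(name: str) -> str:
    """Map a parameter alias (Km, delta_p, lam1, ...) to its canonical slot."""
    name = PARAM_ALIASES.get(name, name)
    if name not in _CANONICAL:
        raise ConfigurationError(
            f"unknown parameter {name!r}; expected one of {_CANONICAL} or aliases "
            f"{tuple(PARAM_ALIASES)}")
    return name


@dataclass(frozen=True)
class GeneParams:
    """One cell's kinetic rate vector.  M2's (Km, Kp, delta_m, delta_p) map
    onto (KN, KP, deltaM, deltaP); rates of unused reactions stay 0."""

    lam: float = 0.0
    mu: float = 0.0
    lam2: float = 0.0
    KN: float = 0.0
    KM: float = 0.0
    KP: float = 0.0
    deltaM: float = 1.0
    deltaP: float = 0.0

    def __post_init__(self) -> None:
        for name in _CANONICAL:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"rate {name} must be finite and >= 0, got {v!r}")

    @classmethod
    def of(cls, **kw) -> "GeneParams":
        """Construct accepting aliases, e.g. ``GeneParams.of(Km=50, Kp=2, delta_p=0.1)``."""
        return cls(**{canonical_param(k): v for k, v in kw.items()})

    def replace(self, **kw) -> "GeneParams":
        d = asdict(self)
        d.update({canonical_param(k): v for k, v in kw.items()})
        return GeneParams(**d)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _CANONICAL], dtype=float)


@dataclass(frozen=True)
class CellCycleSpec:
    """Erlang-phased cell cycle: time to replication ~ Erlang(replication_shape,
    rate), replication to division ~ Erlang(division_shape, rate); the
    activation rate is multiplied by ``dosage_factor`` while the gene is
    replicated."""

    rate: float = 0.0   # 0 ties the phase rate to the cell's activation rate
    replication_shape: int = 12
    division_shape: int = 12
    dosage_factor: float = 0.7

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError("cell-cycle rate must be >= 0 (0 = use lam)")
        if not (0 < self.dosage_factor <= 1):
            raise ParameterError("dosage factor must be in (0, 1]")


@dataclass(frozen=True)
class ModelSpec:
    """Which reaction network plus structural options."""

    network: str
    maturation: str = "rate"            # rate | fixed | erlang
    delay: float | tuple = 0.0          # fixed: time; erlang: (shape, rate)
    cell_cycle: CellCycleSpec | None = None

    def __post_init__(self) -> None:
        if self.network not in _NETWORKS:
            raise ConfigurationError(
                f"unknown network {self.network!r}; expected one of {tuple(_NETWORKS)}")
        if self.maturation not in ("rate", "fixed", "erlang"):
            raise ConfigurationError(f"unknown maturation kind {self.maturation!r}")
        if self.maturation != "rate" and self.network not in _HAS_NASCENT:
            raise ConfigurationError(
                f"maturation delays need a nascent species; {self.network} has none")
        if self.maturation == "fixed" and not float(self.delay) > 0:
            raise ConfigurationError("fixed maturation needs delay > 0")
        if self.maturation == "erlang":
            shape, rate = self.delay
            if shape < 1 or rate <= 0:
                raise ConfigurationError("erlang maturation needs shape >= 1 and rate > 0")
        if self.cell_cycle is not None and self.network != "MS3":
            raise ConfigurationError("cell-cycle features are supported on the MS3 network")

    @property
    def code(self) -> int:
        return _NETWORKS[self.network]

    @property
    def delay_code(self) -> tuple[int, float, float]:
        if self.maturation == "rate":
            return 0, 0.0, 0.0
        if self.maturation == "fixed":
            return 1, float(self.delay), 0.0
        shape, rate = self.delay
        return 2, float(shape), float(rate)

    @property
    def has_protein(self) -> bool:
        return self.network in _HAS_PROTEIN

    @property
    def has_nascent(self) -> bool:
        return self.network in _HAS_NASCENT

    def to_dict(self) -> dict:
        d = {"network": self.network, "maturation": self.maturation}
        if self.maturation != "rate":
            d["delay"] = list(self.delay) if self.maturation == "erlang" else self.delay
        if self.cell_cycle is not None:
            d["cell_cycle"] = asdict(self.cell_cycle)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        cc = d.get("cell_cycle")
        delay = d.get("delay", 0.0)
        if isinstance(delay, list):
            delay = tuple(delay)
        return cls(d["network"], d.get("maturation", "rate"), delay,
                   CellCycleSpec(**cc) if cc else None)


def default_t_end(model: ModelSpec, params: GeneParams) -> float:
    """Relaxation horizon: 15 mature-mRNA lifetimes, extended to 10 protein
    lifetimes whenever the network produces protein."""
    if model.has_protein and params.KP > 0 and params.deltaP > 0:
        return max(15.0, 10.0 / params.deltaP)
    return 15.0


# ---------------------------------------------------------------------------
# Exact SSA core (single gene copy, optional maturation delay queue)
# ---------------------------------------------------------------------------

_PEND_CAP = 16384


@njit(cache=False)
def _ssa_run(network, lam, mu, lam2, kN, kM, kP, dM, dP,
             delay_kind, d1, d2, t_end, seed, s, n, m, p):  # pragma: no cover
    np.random.seed(seed)
    pend = np.empty(_PEND_CAP, np.float64)
    npend = 0
    t = 0.0
    while True:
        a_on = 0.0
        a_off = 0.0
        a_pause = 0.0
        a_tx = 0.0
        if network == 3 or network == 4:
            if s == 0:
                a_on = lam
            else:
                a_off = mu
            if s == 1:
                a_tx = kN
        elif network == 5:
            if s == 0:
                a_on = lam
            else:
                a_off = mu
            if s == 1:
                a_pause = lam2
            elif s == 2:
                a_tx = kN
        else:
            a_tx = kN
        a_mat = kM * n if delay_kind == 0 else 0.0
        a_dm = dM * m
        a_tl = kP * m
        a_dp = dP * p
        atot = a_on + a_off + a_pause + a_tx + a_mat + a_dm + a_tl + a_dp

        tnext = 1.0e300
        imin = -1
        for i in range(npend):
            if pend[i] < tnext:
                tnext = pend[i]
                imin = i

        if atot <= 0.0 and imin < 0:
            break
        tr = t + np.random.exponential(1.0 / atot) if atot > 0.0 else 1.0e300
        if tr >= t_end and tnext >= t_end:
            break
        if tnext < tr:
            t = tnext
            pend[imin] = pend[npend - 1]
            npend -= 1
            n -= 1
            m += 1
            continue
        t = tr
        u = np.random.random() * atot
        if u < a_on:
            s = 1
        elif u < a_on + a_off:
            s = 0
        elif u < a_on + a_off + a_pause:
            s = 2
        elif u < a_on + a_off + a_pause + a_tx:
            if network == 2 or network == 3:
                m += 1
            else:
                n += 1
                if network == 5:
                    s = 1
                if delay_kind == 1:
                    if npend >= _PEND_CAP:
                        raise RuntimeError("maturation queue overflow")
                    pend[npend] = t + d1
                    npend += 1
                elif delay_kind == 2:
                    if npend >= _PEND_CAP:
                        raise RuntimeError("maturation queue overflow")
                    pend[npend] = t + np.random.gamma(d1, 1.0 / d2)
                    npend += 1
        elif u < a_on + a_off + a_pause + a_tx + a_mat:
            n -= 1
            m += 1
        elif u < a_on + a_off + a_pause + a_tx + a_mat + a_dm:
            m -= 1
        elif u < a_on + a_off + a_pause + a_tx + a_mat + a_dm + a_tl:
            p += 1
        else:
            p -= 1
    return s, n, m, p


# ---------------------------------------------------------------------------
# Cell-cycle core (MS3, up to two gene copies, shared external schedule)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _ssa_cc(lam1, mu1, lam2, kN, kM, kP, dM, dP,
            delay_kind, d1, d2,
            ev_times, ev_kinds, t_sample, dosage, seed,
            div_pre, div_post):  # pragma: no cover
    """MS3 network with replication (kind 1) / division (kind 2) events.

    Runs until t_sample and returns the state there.  div_pre/div_post
    collect (nascent, mature, protein) around each division for diagnostics.
    """
    np.random.seed(seed)
    s0 = 0
    s1 = 0
    ncop = 1
    n = 0
    m = 0
    p = 0
    lam_eff = lam1
    pend = np.empty(_PEND_CAP, np.float64)
    npend = 0
    t = 0.0
    iev = 0
    ndiv = 0
    nev = ev_times.shape[0]
    while True:
        t_stop = t_sample
        kind = 0
        if iev < nev and ev_times[iev] < t_stop:
            t_stop = ev_times[iev]
            kind = ev_kinds[iev]

        # SSA within [t, t_stop)
        while True:
            a = np.zeros(8)
            # per-copy promoter channels, copy 1
            if s0 == 0:
                a[0] = lam_eff
            else:
                a[1] = mu1
            if s0 == 1:
                a[2] = lam2
            elif s0 == 2:
                a[3] = kN
            if ncop == 2:
                if s1 == 0:
                    a[4] = lam_eff
                else:
                    a[5] = mu1
                if s1 == 1:
                    a[6] = lam2
                elif s1 == 2:
                    a[7] = kN
            a_mat = kM * n if delay_kind == 0 else 0.0
            a_dm = dM * m
            a_tl = kP * m
            a_dp = dP * p
            atot = a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7] \
                + a_mat + a_dm + a_tl + a_dp

            tnext = 1.0e300
            imin = -1
            for i in range(npend):
                if pend[i] < tnext:
                    tnext = pend[i]
                    imin = i
            tr = t + np.random.exponential(1.0 / atot) if atot > 0.0 else 1.0e300
            if tr >= t_stop and tnext >= t_stop:
                t = t_stop
                break
            if tnext < tr:
                t = tnext
                pend[imin] = pend[npend - 1]
                npend -= 1
                n -= 1
                m += 1
                continue
            t = tr
            u = np.random.random() * atot
            schedule = False
            if u < a[0]:
                s0 = 1
            elif u < a[0] + a[1]:
                s0 = 0
            elif u < a[0] + a[1] + a[2]:
                s0 = 2
            elif u < a[0] + a[1] + a[2] + a[3]:
                n += 1
                s0 = 1
                schedule = True
            elif u < a[0] + a[1] + a[2] + a[3] + a[4]:
                s1 = 1
            elif u < a[0] + a[1] + a[2] + a[3] + a[4] + a[5]:
                s1 = 0
            elif u < a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6]:
                s1 = 2
            elif u < a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7]:
                n += 1
                s1 = 1
                schedule = True
            else:
                rest = u - (a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7])
                if rest < a_mat:
                    n -= 1
                    m += 1
                elif rest < a_mat + a_dm:
                    m -= 1
                elif rest < a_mat + a_dm + a_tl:
                    p += 1
                else:
                    p -= 1
            if schedule and delay_kind > 0:
                if npend >= _PEND_CAP:
                    raise RuntimeError("maturation queue overflow")
                if delay_kind == 1:
                    pend[npend] = t + d1
                else:
                    pend[npend] = t + np.random.gamma(d1, 1.0 / d2)
                npend += 1

        if kind == 0:       # reached the sampling time
            break
        if kind == 1:       # replication: duplicate the gene, dosage-compensate
            ncop = 2
            s1 = s0
            lam_eff = lam1 * dosage
        else:               # division: thin molecules, follow one daughter
            div_pre[ndiv, 0] = n
            div_pre[ndiv, 1] = m
            div_pre[ndiv, 2] = p
            if delay_kind == 0:
                n = np.random.binomial(n, 0.5) if n > 0 else 0
            else:
                keep = 0
                for i in range(npend):
                    if np.random.random() < 0.5:
                        pend[keep] = pend[i]
                        keep += 1
                npend = keep
                n = npend
            m = np.random.binomial(m, 0.5) if m > 0 else 0
            p = np.random.binomial(p, 0.5) if p > 0 else 0
            div_post[ndiv, 0] = n
            div_post[ndiv, 1] = m
            div_post[ndiv, 2] = p
            ndiv += 1
            ncop = 1
            lam_eff = lam1
        iev += 1
    return s0, n, m, p, ncop, lam_eff, ndiv


# ---------------------------------------------------------------------------
# Python surface
# ---------------------------------------------------------------------------

def propensity_table(model: ModelSpec, params: GeneParams, state) -> dict[str, float]:
    """Exact mass-action propensities at ``state = (gene_state, nascent,
    mature, protein)``; mirrors the SSA core channel for channel."""
    s, n, m, p = state
    q = params
    net = model.network
    delay_kind, _, _ = model.delay_code
    a: dict[str, float] = {}
    if net in ("M3", "M4"):
        a["activate"] = q.lam if s == 0 else 0.0
        a["deactivate"] = q.mu if s == 1 else 0.0
        a["transcribe"] = q.KN if s == 1 else 0.0
    elif net == "MS3":
        a["activate"] = q.lam if s == 0 else 0.0
        a["deactivate"] = q.mu if s in (1, 2) else 0.0
        a["pause"] = q.lam2 if s == 1 else 0.0
        a["transcribe"] = q.KN if s == 2 else 0.0
    else:
        a["transcribe"] = q.KN
    if model.has_nascent and delay_kind == 0:
        a["mature"] = q.KM * n
    a["mature-decay"] = q.deltaM * m
    if model.has_protein:
        a["translate"] = q.KP * m
        a["protein-decay"] = q.deltaP * p
    return a


def _core_seed(seq: np.ndarray, i: int) -> int:
    return int(seq[i]) & 0x7FFFFFFF


def ssa_snapshot(model: ModelSpec, params: GeneParams, t_end: float | None = None,
                 seed: int = 0) -> dict[str, int]:
    """One exact-SSA realisation from the empty/inactive initial state,
    returning the species counts at ``t_end``."""
    if t_end is None:
        t_end = default_t_end(model, params)
    dk, d1, d2 = model.delay_code
    s, n, m, p = _ssa_run(model.code, params.lam, params.mu, params.lam2,
                          params.KN, params.KM, params.KP, params.deltaM,
                          params.deltaP, dk, d1, d2, float(t_end),
                          int(seed) & 0x7FFFFFFF, 0, 0, 0, 0)
    return {"gene_state": int(s), "nascent": int(n), "mature": int(m), "protein": int(p)}


@dataclass
class PopulationSample:
    """Per-cell steady-state counts plus the parameter draws that made them."""

    data: pd.DataFrame
    model: ModelSpec
    noise: dict[str, NoiseSpec] = field(default_factory=dict)
    seed: int | None = None
    t_end: float | str = 15.0

    def __len__(self) -> int:
        return len(self.data)

    def counts(self, species: str, copy: int = 1) -> np.ndarray:
        col = species if copy == 1 else f"{species}2"
        return self.data[col].to_numpy()

    def write(self, path) -> None:
        """Delimited text (one row per cell) plus a JSON side-car with the
        model spec, noise specs and seed.  17 significant digits guarantee a
        bit-exact float round trip."""
        self.data.to_csv(path, index=False, float_format="%.17g")
        meta = {
            "model": self.model.to_dict(),
            "noise": {k: {"family": v.family, "params": list(v.params)}
                      for k, v in self.noise.items()},
            "seed": self.seed,
            "t_end": self.t_end,
        }
        with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, path) -> "PopulationSample":
        data = pd.read_csv(path, float_precision="round_trip")
        for c in _CANONICAL:  # constant rate columns round-trip as ints otherwise
            if c in data.columns:
                data[c] = data[c].astype(float)
        try:
            with open(str(path) + ".meta.json", encoding="utf-8") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            return cls(data, ModelSpec("M1"))
        noise = {k: NoiseSpec(v["family"], tuple(v["params"]))
                 for k, v in meta.get("noise", {}).items()}
        return cls(data, ModelSpec.from_dict(meta["model"]), noise,
                   meta.get("seed"), meta.get("t_end", 15.0))


def _draw_parameters(mean_params: GeneParams, noise: Mapping[str, NoiseSpec],
                     n_cells: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    canon = {}
    for name, spec in noise.items():
        cname = canonical_param(name)
        if cname in canon:
            raise ConfigurationError(f"duplicate noise spec for parameter {cname!r}")
        canon[cname] = spec
    for cname, spec in canon.items():
        target = getattr(mean_params, cname)
        if target > 0 and abs(spec.mean() - target) > 1e-6 * max(target, 1.0):
            raise ConfigurationError(
                f"noise spec mean {spec.mean():.6g} for {cname!r} does not match "
                f"mean parameter {target:.6g}")
    for cname in _CANONICAL:
        if cname in canon:
            cols[cname] = canon[cname].sample(n_cells, rng)
        else:
            cols[cname] = np.full(n_cells, getattr(mean_params, cname))
    return cols


def simulate_population(model: ModelSpec, mean_params: GeneParams,
                        noise: Mapping[str, NoiseSpec] | None = None,
                        n_cells: int = 500, dual_reporter: bool = False,
                        seed: int | None = None, t_end: float | None = None,
                        n_cycles: int = 10) -> PopulationSample:
    """Steady-state snapshot of ``n_cells`` cells with static extrinsic noise.

    Each cell draws one parameter vector (independent draws across
    parameters), relaxes from the empty state and is observed once.  With
    ``dual_reporter=True`` each cell runs two conditionally independent SSA
    realisations sharing its parameter draw; the second copy's counts appear
    in ``nascent2``/``mature2``/``protein2`` columns.
    """
    if n_cells < 1:
        raise ConfigurationError("need n_cells >= 1")
    noise = dict(noise or {})
    if isinstance(seed, np.random.SeedSequence):
        ss, seed = seed, seed.entropy
    else:
        ss = np.random.SeedSequence(seed)
    param_child, sim_child = ss.spawn(2)
    rng = np.random.default_rng(param_child)
    cols = _draw_parameters(mean_params, noise, n_cells, rng)
    seeds = sim_child.generate_state(2 * n_cells, dtype=np.uint32)

    if model.cell_cycle is not None:
        return _simulate_population_cc(model, cols, n_cells, dual_reporter,
                                       seeds, rng, noise, seed, n_cycles)

    dk, d1, d2 = model.delay_code
    code = model.code
    if t_end is None:
        if model.has_protein:
            with np.errstate(divide="ignore"):
                te = np.where((cols["KP"] > 0) & (cols["deltaP"] > 0),
                              np.maximum(15.0, 10.0 / np.maximum(cols["deltaP"], 1e-12)),
                              15.0)
        else:
            te = np.full(n_cells, 15.0)
    else:
        te = np.full(n_cells, float(t_end))

    out = np.zeros((n_cells, 8 if dual_reporter else 4), dtype=np.int64)
    for i in range(n_cells):
        res = _ssa_run(code, cols["lam"][i], cols["mu"][i], cols["lam2"][i],
                       cols["KN"][i], cols["KM"][i], cols["KP"][i],
                       cols["deltaM"][i], cols["deltaP"][i],
                       dk, d1, d2, te[i], _core_seed(seeds, 2 * i), 0, 0, 0, 0)
        out[i, :4] = res
        if dual_reporter:
            res2 = _ssa_run(code, cols["lam"][i], cols["mu"][i], cols["lam2"][i],
                            cols["KN"][i], cols["KM"][i], cols["KP"][i],
                            cols["deltaM"][i], cols["deltaP"][i],
                            dk, d1, d2, te[i], _core_seed(seeds, 2 * i + 1), 0, 0, 0, 0)
            out[i, 4:] = res2

    frame = {"cell": np.arange(n_cells),
             "gene_state": out[:, 0], "nascent": out[:, 1],
             "mature": out[:, 2], "protein": out[:, 3]}
    if dual_reporter:
        frame.update({"gene_state2": out[:, 4], "nascent2": out[:, 5],
                      "mature2": out[:, 6], "protein2": out[:, 7]})
    for cname in _CANONICAL:
        frame[cname] = cols[cname]
    return PopulationSample(pd.DataFrame(frame), model, noise, seed,
                            t_end if t_end is not None else "auto")


def _cc_schedule(cc: CellCycleSpec, rate: float, n_cycles: int,
                 rng: np.random.Generator):
    """Absolute replication/division times for ``n_cycles`` cycles."""
    rep = rng.gamma(cc.replication_shape, 1.0 / rate, size=n_cycles)
    div = rng.gamma(cc.division_shape, 1.0 / rate, size=n_cycles)
    times = np.empty(2 * n_cycles)
    kinds = np.empty(2 * n_cycles, dtype=np.int64)
    t = 0.0
    for c in range(n_cycles):
        t += rep[c]
        times[2 * c] = t
        kinds[2 * c] = 1
        t += div[c]
        times[2 * c + 1] = t
        kinds[2 * c + 1] = 2
    return times, kinds


def simulate_cell_cycle(model: ModelSpec, params: GeneParams, n_cycles: int = 10,
                        seed: int = 0, sample_phase: str = "any",
                        return_divisions: bool = False):
    """Snapshot of one cell simulated through ``n_cycles`` cell cycles.

    The first ``n_cycles - 1`` cycles are burn-in; the snapshot time is
    uniform within the final cycle (``sample_phase`` can pin it to the
    ``pre-replication`` or ``post-replication`` half for diagnostics).
    Returns a dict of counts plus ``gene_copies`` and the effective
    activation rate at the sampling time; with ``return_divisions`` also the
    per-division (pre, post) count triples actually executed.
    """
    if model.cell_cycle is None:
        raise ConfigurationError("model has no cell-cycle spec")
    if n_cycles < 3:
        raise ConfigurationError("need n_cycles >= 3 (burn-in)")
    cc = model.cell_cycle
    rng = np.random.default_rng(seed)
    rate = cc.rate if cc.rate > 0 else params.lam
    times, kinds = _cc_schedule(cc, rate, n_cycles, rng)
    start = times[-3] if n_cycles > 1 else 0.0  # last division before final cycle
    if sample_phase == "any":
        t_sample = rng.uniform(start, times[-1])
    elif sample_phase == "pre-replication":
        t_sample = rng.uniform(start, times[-2])
    elif sample_phase == "post-replication":
        t_sample = rng.uniform(times[-2], times[-1])
    else:
        raise ConfigurationError(f"unknown sample_phase {sample_phase!r}")
    dk, d1, d2 = model.delay_code
    div_pre = np.zeros((n_cycles, 3), dtype=np.int64)
    div_post = np.zeros((n_cycles, 3), dtype=np.int64)
    s, n, m, p, ncop, lam_eff, ndiv = _ssa_cc(
        params.lam, params.mu, params.lam2, params.KN, params.KM, params.KP,
        params.deltaM, params.deltaP, dk, d1, d2, times, kinds,
        t_sample, cc.dosage_factor, int(seed) & 0x7FFFFFFF, div_pre, div_post)
    out = {"gene_state": int(s), "nascent": int(n), "mature": int(m),
           "protein": int(p), "gene_copies": int(ncop), "lam_eff": float(lam_eff)}
    if return_divisions:
        return out, div_pre[:ndiv], div_post[:ndiv]
    return out


def _simulate_population_cc(model, cols, n_cells, dual_reporter, seeds, rng,
                            noise, seed, n_cycles):
    cc = model.cell_cycle
    dk, d1, d2 = model.delay_code
    out = np.zeros((n_cells, 8 if dual_reporter else 4), dtype=np.int64)
    copies = np.zeros(n_cells, dtype=np.int64)
    dummy_pre = np.zeros((n_cycles, 3), dtype=np.int64)
    dummy_post = np.zeros((n_cycles, 3), dtype=np.int64)
    for i in range(n_cells):
        # cycle rate tied to the cell's activation rate unless set explicitly
        rate = cc.rate if cc.rate > 0 else cols["lam"][i]
        times, kinds = _cc_schedule(cc, rate, n_cycles, rng)
        t_sample = rng.uniform(times[-3], times[-1])
        args = (cols["lam"][i], cols["mu"][i], cols["lam2"][i], cols["KN"][i],
                cols["KM"][i], cols["KP"][i], cols["deltaM"][i], cols["deltaP"][i],
                dk, d1, d2, times, kinds, t_sample, cc.dosage_factor)
        s, n, m, p, ncop, _, _ = _ssa_cc(*args, _core_seed(seeds, 2 * i),
                                         dummy_pre, dummy_post)
        out[i, :4] = (s, n, m, p)
        copies[i] = ncop
        if dual_reporter:
            # same cell: shared schedule and snapshot time, independent noise
            s2, n2, m2, p2, _, _, _ = _ssa_cc(*args, _core_seed(seeds, 2 * i + 1),
                                              dummy_pre, dummy_post)
            out[i, 4:] = (s2, n2, m2, p2)
    frame = {"cell": np.arange(n_cells),
             "gene_state": out[:, 0], "nascent": out[:, 1],
             "mature": out[:, 2], "protein": out[:, 3],
             "gene_copies": copies}
    if dual_reporter:
        frame.update({"gene_state2": out[:, 4], "nascent2": out[:, 5],
                      "mature2": out[:, 6], "protein2": out[:, 7]})
    for cname in _CANONICAL:
        frame[cname] = cols[cname]
    return PopulationSample(pd.DataFrame(frame), model, dict(noise), seed, "cell-cycle")
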