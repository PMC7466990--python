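"""Demographic inference for two-population divergence with epoch-switching
migration: SFS simulation, composite likelihood, ECM-style fitting, Akaike
model selection, parametric bootstrap, and derived quantities.

Three nested candidate histories are supported, all sharing a split of an
ancestral population (size ANCSIZE) into wild and domestic demes T1
generations ago:

* ``no_migration`` — pure divergence, 4 free parameters.
* ``constant_migration`` — constant asymmetric gene flow after the split,
  6 free parameters.
* ``changing_migration`` — gene flow switches matrices T2 generations ago,
  9 free parameters.

The likelihood is the multinomial composite likelihood of the folded joint
SFS, with the monomorphic class included: at a fixed per-generation
mutation rate, the polymorphic fraction of callable sites is what makes
absolute sizes and times identifiable. Maximization is block-coordinate
("conditional maximization") ascent over {sizes}, {times}, {rates} with a
log-scale line search per parameter and common random numbers within a
cycle so that Monte-Carlo noise cancels in comparisons.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from goosepop.coalescent import expected_branch_config_lengths
from goosepop.sfs import Sfs2D, fold

MODEL_IDS = ("no_migration", "constant_migration", "changing_migration")
_MODEL_ALIASES = {
    "i": "no_migration",
    "ii": "constant_migration",
    "iii": "changing_migration",
}
N_FREE_PARAMS = {"no_migration": 4, "constant_migration": 6, "changing_migration": 9}

#: Per-site per-generation mutation rate used throughout (pink-footed goose
#: pedigree-scale estimate applied to graylags).
DEFAULT_MU = 1.38e-7
DEFAULT_GENERATION_TIME = 3.0

P_FLOOR = 1e-10

#: fraction of expected polymorphic mass spread uniformly over cells while
#: searching (removes the zero-cell bias against broad spectra); final
#: likelihoods are always exact
_SEARCH_SMOOTH = 0.01


@dataclass(frozen=True)
class DemographicParams:
    """Parameters of the two-deme divergence model (generations, diploid sizes).

    ``m1_*`` apply in the older epoch [T2, T1), ``m2_*`` in the recent epoch
    [0, T2). ``m_xy`` is the per-generation fraction of deme y replaced by
    migrants from deme x (w = wild, d = domestic), so the expected number of
    migrants into y per generation is N_y * m_xy.
    """

    anc_size: float
    t1: float
    n_wild: float
    n_dom: float
    m1_wd: float = 0.0
    m1_dw: float = 0.0
    t2: float = 0.0
    m2_wd: float = 0.0
    m2_dw: float = 0.0
    mu: float = DEFAULT_MU
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        if min(self.anc_size, self.n_wild, self.n_dom) < 1:
            raise ValueError("population sizes must be >= 1")
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("times must be >= 0")
        if self.t2 > self.t1:
            raise ValueError("T2 must not exceed T1")
        for m in (self.m1_wd, self.m1_dw, self.m2_wd, self.m2_dw):
            if not 0.0 <= m < 1.0:
                raise ValueError("migration rates must be in [0, 1)")
        if self.mu <= 0:
            raise ValueError("mutation rate must be positive")


#: Maximum-likelihood point estimates for the preferred (changing-migration)
#: goose domestication history; used as defaults for simulation studies.
GOOSE_MLE = DemographicParams(
    anc_size=1112,
    t1=5319,
    n_wild=2504,
    n_dom=959,
    m1_wd=4.25e-4,
    m1_dw=5.35e-4,
    t2=159,
    m2_wd=1.72e-3,
    m2_dw=6.69e-4,
)

#: Sample sizes (allele copies) behind the study's folded joint SFS:
#: 11 wild and 15 domestic diploids.
WILD_CHROMS = 22
DOM_CHROMS = 30
#: Callable-site totals behind the observed SFS.
TOTAL_SITES = 1_681_316
MONOMORPHIC_SITES = 1_675_087
POLYMORPHIC_SITES = 6_229


@dataclass(frozen=True)
class Model:
    """A validated model: identifier, parameters and canonical event list
    (backward in time)."""

    model_id: str
    params: DemographicParams
    events: tuple = ()

    @property
    def n_free_params(self) -> int:
        return N_FREE_PARAMS[self.model_id]


def canonical_model_id(model_id: str) -> str:
    mid = _MODEL_ALIASES.get(model_id, model_id)
    if mid not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    return mid


def build_model(model_id: str, params: DemographicParams) -> Model:
    """Validate parameters against a model's constraints.

    ``no_migration`` requires all migration rates zero; ``constant_migration``
    requires the two epochs to carry identical rates (T2 is unused and forced
    to zero so the event list is canonical).
    """
    mid = canonical_model_id(model_id)
    p = params
    if mid == "no_migration":
        if any(m != 0 for m in (p.m1_wd, p.m1_dw, p.m2_wd, p.m2_dw)):
            raise ValueError("no_migration model requires all migration rates = 0")
        p = replace(p, t2=0.0)
    elif mid == "constant_migration":
        if (p.m2_wd, p.m2_dw) != (p.m1_wd, p.m1_dw):
            raise ValueError(
                "constant_migration model requires identical rates in both epochs"
            )
        p = replace(p, t2=0.0, m2_wd=p.m1_wd, m2_dw=p.m1_dw)
    events = []
    if p.t2 > 0:
        events.append(("switch_migration", p.t2, (p.m1_wd, p.m1_dw)))
    events.append(("merge_into_ancestor", p.t1, p.anc_size))
    return Model(model_id=mid, params=p, events=tuple(events))


def simulate_sfs(
    model: Model,
    n_sites: int,
    n_wild_chroms: int = WILD_CHROMS,
    n_dom_chroms: int = DOM_CHROMS,
    mu: float | None = None,
    n_reps: int = 5000,
    seed: int = 0,
    mode: str = "expected",
    folded: bool = True,
) -> Sfs2D:
    """Simulate the joint SFS under a model.

    ``expected`` mode returns the normalized expected spectrum scaled by
    ``n_sites`` (the infinite-sites expectation of Poisson mutation
    dropping); ``sampled`` mode draws site counts multinomially around it,
    emulating a finite observed dataset.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if mode not in ("expected", "sampled"):
        raise ValueError("mode must be 'expected' or 'sampled'")
    mu = model.params.mu if mu is None else mu
    lengths = expected_branch_config_lengths(
        model.params, n_wild_chroms, n_dom_chroms, n_reps, seed
    )
    probs = mu * lengths  # per-site probability of each polymorphic cell
    total_poly = probs.sum()
    if total_poly >= 1.0:
        raise ValueError(
            "expected polymorphism exceeds one site per site; mu or branch "
            "lengths are out of the infinite-sites regime"
        )
    counts = probs * n_sites
    mono = n_sites - counts.sum()
    if mode == "sampled":
        rng = np.random.default_rng(seed + 1)
        flat = np.concatenate([counts.ravel(), [mono]])
        draw = rng.multinomial(int(n_sites), flat / flat.sum())
        counts = draw[:-1].reshape(counts.shape).astype(float)
        mono = float(draw[-1])
    sfs = Sfs2D(counts=counts, monomorphic=float(mono), folded=False)
    return fold(sfs) if folded else sfs


def composite_log_likelihood(observed: Sfs2D, expected: Sfs2D) -> float:
    """Multinomial composite log-likelihood of observed counts under the
    expected spectrum's cell probabilities (monomorphic class included).

    Expected-cell probabilities of zero under observed support are floored
    at 1e-10 (finite simulation can miss rare cells)."""
    if observed.counts.shape != expected.counts.shape:
        raise ValueError("SFS dimensions do not match")
    if observed.folded != expected.folded:
        raise ValueError("folded/unfolded mismatch between observed and expected")
    p_cells, p_mono = expected.normalized()
    lncl = 0.0
    obs = observed.counts
    mask = obs > 0
    p_used = np.where(p_cells[mask] > 0, p_cells[mask], P_FLOOR)
    lncl += float((obs[mask] * np.log(p_used)).sum())
    if observed.monomorphic > 0:
        lncl += observed.monomorphic * math.log(max(p_mono, P_FLOOR))
    return lncl


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_SIZE_PARAMS = ("anc_size", "n_wild", "n_dom")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "anc_size": (50.0, 50_000.0),
    "n_wild": (50.0, 50_000.0),
    "n_dom": (50.0, 50_000.0),
    "t1": (50.0, 50_000.0),
    "t2": (5.0, 50_000.0),
    "m1_wd": (1e-7, 2e-2),
    "m1_dw": (1e-7, 2e-2),
    "m2_wd": (1e-7, 2e-2),
    "m2_dw": (1e-7, 2e-2),
}


@dataclass(frozen=True)
class FitSettings:
    """Optimization effort knobs.

    The desk-scale defaults (5,000 coalescent replicates per likelihood,
    10 conditional-maximization cycles, 20 restarts) trade precision for
    turnaround; the ``paper`` profile (100,000 replicates, 40 cycles, 100
    restarts) reproduces full-scale estimation effort.
    """

    n_reps: int = 5000
    n_cycles: int = 10
    n_restarts: int = 20
    polish_rounds: int = 3
    polish_maxiter: int = 250
    #: extra profile scan over the epoch-switch time with re-optimization of
    #: the recent-epoch rates; T2 is the weakest-identified parameter and
    #: rival (T2, M2) modes can sit within a few log-likelihood units
    refine_epoch: bool = False

    @classmethod
    def profile(cls, name: str) -> "FitSettings":
        if name == "desk":
            return cls()
        if name == "paper":
            return cls(n_reps=100_000, n_cycles=40, n_restarts=100)
        if name == "fast":
            return cls(n_reps=1500, n_cycles=3, n_restarts=2, polish_rounds=2,
                       polish_maxiter=150)
        raise ValueError(f"unknown profile {name!r}")


@dataclass
class FitResult:
    model_id: str
    params: DemographicParams
    log_composite_likelihood: float
    n_free_params: int
    aic: float
    akaike_weight: float | None = None
    bootstrap_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    observed_fingerprint: str = ""

    def to_dict(self) -> dict:
        out = {
            "model": self.model_id,
            "lnCL": self.log_composite_likelihood,
            "k": self.n_free_params,
            "AIC": self.aic,
            "akaike_weight": self.akaike_weight,
            "parameters": {
                "ANCSIZE": self.params.anc_size,
                "T1": self.params.t1,
                "N_WILD": self.params.n_wild,
                "N_DOM": self.params.n_dom,
                "M1_WD": self.params.m1_wd,
                "M1_DW": self.params.m1_dw,
                "T2": self.params.t2,
                "M2_WD": self.params.m2_wd,
                "M2_DW": self.params.m2_dw,
            },
        }
        if self.bootstrap_ci:
            out["bootstrap_95CI"] = {
                k: list(v) for k, v in self.bootstrap_ci.items()
            }
        return out


def _fingerprint(sfs: Sfs2D) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(sfs.counts).tobytes())
    h.update(np.float64(sfs.monomorphic).tobytes())
    return h.hexdigest()[:16]


def _tie_constant_migration(p: DemographicParams) -> DemographicParams:
    return replace(p, m2_wd=p.m1_wd, m2_dw=p.m1_dw, t2=0.0)


def _param_blocks(model_id: str) -> list[list[str]]:
    sizes = ["anc_size", "n_wild", "n_dom"]
    if model_id == "no_migration":
        return [sizes, ["t1"]]
    if model_id == "constant_migration":
        return [sizes, ["t1"], ["m1_wd", "m1_dw"]]
    return [sizes, ["t1", "t2"], ["m1_wd", "m1_dw", "m2_wd", "m2_dw"]]


def _apply(p: DemographicParams, name: str, value: float, model_id: str) -> DemographicParams:
    value = float(value)
    if name == "t2":
        value = min(value, p.t1)
    if name == "t1":
        p = replace(p, t2=min(p.t2, value))
    p = replace(p, **{name: value})
    if model_id == "constant_migration":
        p = _tie_constant_migration(p)
    return p


def _lncl(
    observed: Sfs2D,
    model_id: str,
    p: DemographicParams,
    n_reps: int,
    seed: int,
    smooth: float = 0.0,
) -> float:
    """Composite log-likelihood of ``observed`` under a parameter point.

    ``smooth`` > 0 spreads that fraction of the expected polymorphic mass
    uniformly over the cells before normalization. Finite simulation leaves
    rare cells empty, and the hard floor then penalizes exactly the models
    with broad spectra; the smoothed objective removes that search bias.
    The final scoring of fits always uses the exact (unsmoothed) likelihood.
    """
    model = build_model(model_id, p)
    exp_sfs = simulate_sfs(
        model,
        n_sites=int(round(observed.total_sites)),
        n_wild_chroms=observed.n1,
        n_dom_chroms=observed.n2,
        mu=p.mu,
        n_reps=n_reps,
        seed=seed,
        mode="expected",
        folded=observed.folded,
    )
    if smooth > 0.0:
        poly = exp_sfs.counts.sum()
        if poly > 0:
            n1, n2 = exp_sfs.n1, exp_sfs.n2
            pooled = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
            valid = np.ones_like(exp_sfs.counts, dtype=bool)
            if exp_sfs.folded:
                valid &= 2 * pooled <= n1 + n2
            valid[0, 0] = False
            valid[n1, n2] = False
            counts = exp_sfs.counts + (smooth * poly / valid.sum()) * valid
            exp_sfs = Sfs2D(
                counts=counts,
                monomorphic=max(exp_sfs.monomorphic - smooth * poly, 0.0),
                folded=exp_sfs.folded,
            )
    return composite_log_likelihood(observed, exp_sfs)


def _draw_start(
    model_id: str, bounds: dict[str, tuple[float, float]], rng: np.random.Generator, mu: float
) -> DemographicParams:
    vals: dict[str, float] = {}
    names = (
        _SIZE_PARAMS
        + ("t1",)
        + (("m1_wd", "m1_dw") if model_id != "no_migration" else ())
        + (("t2", "m2_wd", "m2_dw") if model_id == "changing_migration" else ())
    )
    for name in names:
        lo, hi = bounds[name]
        vals[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if "t2" in vals:
        vals["t2"] = min(vals["t2"], vals["t1"])
    p = DemographicParams(
        anc_size=vals["anc_size"],
        t1=vals["t1"],
        n_wild=vals["n_wild"],
        n_dom=vals["n_dom"],
        m1_wd=vals.get("m1_wd", 0.0),
        m1_dw=vals.get("m1_dw", 0.0),
        t2=vals.get("t2", 0.0),
        m2_wd=vals.get("m2_wd", 0.0),
        m2_dw=vals.get("m2_dw", 0.0),
        mu=mu,
    )
    if model_id == "constant_migration":
        p = _tie_constant_migration(p)
    return p


def fit_sfs(
    observed: Sfs2D,
    model_id: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    settings: FitSettings | None = None,
    seed: int = 0,
    mu: float = DEFAULT_MU,
    start: DemographicParams | None = None,
    warm_start: bool = True,
    parent_params: DemographicParams | None = None,
) -> FitResult:
    """Maximize the SFS composite likelihood by conditional (block-coordinate)
    maximization with restarts.

    Each cycle walks the blocks {sizes}, {times}, {rates}; within a block,
    each parameter gets a two-stage log-scale line search. All likelihood
    evaluations in a cycle share one coalescent seed (common random
    numbers), so proposals are compared under identical Monte-Carlo noise.
    Restarts are drawn log-uniform within bounds; the best run wins.
    """
    mid = canonical_model_id(model_id)
    if observed.total_sites <= 0:
        raise ValueError("observed SFS is empty")
    settings = settings or FitSettings()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    rng = np.random.default_rng(seed)
    blocks = _param_blocks(mid)

    best_p: DemographicParams | None = None
    best_ll = -np.inf
    final_seed = int(rng.integers(1, 2**31 - 1))

    # global screening: score a cloud of candidates cheaply under one shared
    # seed, then refine only the most promising ones. The cloud mixes
    # log-uniform draws with warm starts derived from a fit of the nested
    # simpler model (standard practice for nested demographic histories:
    # the simpler model's optimum anchors the richer model's basin).
    screen_seed = int(rng.integers(1, 2**31 - 1))
    screen_reps = settings.n_reps
    candidates = [
        _draw_start(mid, bounds, rng, mu)
        for _ in range(max(12 * settings.n_restarts, 40))
    ]
    if parent_params is not None and mid != "no_migration":
        # the caller supplies the nested model's optimum: that basin is
        # already covered (a richer fit can fall back on the embedded nested
        # point), so explore only the gene-flow-bearing warm grid around it
        candidates = _warm_candidates(mid, parent_params, bounds)
    elif warm_start and mid != "no_migration":
        parent_mid = "no_migration" if mid == "constant_migration" else "constant_migration"
        parent_settings = FitSettings(
            n_reps=settings.n_reps,
            n_cycles=max(settings.n_cycles * 2 // 3, 2),
            n_restarts=max(settings.n_restarts // 2, 1),
            polish_rounds=max(settings.polish_rounds - 1, 1),
            polish_maxiter=settings.polish_maxiter,
        )
        parent = fit_sfs(
            observed, parent_mid, bounds=bounds, settings=parent_settings,
            seed=seed + 7, mu=mu,
        )
        candidates = _warm_candidates(mid, parent.params, bounds) + candidates
    if start is not None:
        p0 = start if mid != "constant_migration" else _tie_constant_migration(start)
        candidates.insert(0, replace(p0, mu=mu))
    scored = sorted(
        ((_lncl(observed, mid, c, screen_reps, screen_seed, smooth=_SEARCH_SMOOTH), i)
         for i, c in enumerate(candidates)),
        reverse=True,
    )
    # greedy diverse selection: screening rank predicts within-basin quality
    # but not which basin wins after refinement, so spread starts across
    # distinct split-time scales rather than taking the overall top block
    starts: list[DemographicParams] = []

    def _t1_close(a: DemographicParams, b: DemographicParams) -> bool:
        return abs(np.log(a.t1) - np.log(b.t1)) < 0.8

    def _mode_close(a: DemographicParams, b: DemographicParams) -> bool:
        if not _t1_close(a, b):
            return False
        if mid == "changing_migration":
            ta, tb = max(a.t2, 1.0), max(b.t2, 1.0)
            if abs(np.log(ta) - np.log(tb)) >= 1.2:
                return False
        return True

    # fill most slots with distinct split-time scales (the dominant basin
    # axis), then spend the rest on distinct migration-shift times, then by
    # plain score
    t1_slots = max(settings.n_restarts - 2, min(2, settings.n_restarts))
    for _, i in scored:
        if len(starts) >= t1_slots:
            break
        c = candidates[i]
        if any(_t1_close(c, s) for s in starts):
            continue
        starts.append(c)
    for _, i in scored:
        if len(starts) >= settings.n_restarts:
            break
        c = candidates[i]
        if c in starts or any(_mode_close(c, s) for s in starts):
            continue
        starts.append(c)
    for _, i in scored:
        if len(starts) >= settings.n_restarts:
            break
        if candidates[i] not in starts:
            starts.append(candidates[i])

    free = list(_free_names(mid))
    for p in starts:
        ll = None
        for cycle in range(settings.n_cycles):
            cycle_seed = int(rng.integers(1, 2**31 - 1))
            span = max(16.0 * (0.5**cycle), 2.0)
            ll = _lncl(observed, mid, p, settings.n_reps, cycle_seed, smooth=_SEARCH_SMOOTH)
            for block in blocks:
                for name in block:
                    p, ll = _line_search(
                        observed, mid, p, name, ll, bounds, span,
                        settings.n_reps, cycle_seed,
                    )
        # simplex refinement within the located basin; replicate counts double
        # each round so late rounds see low-bias likelihoods, while the
        # iteration budget shrinks as the simplex narrows
        maxiter_base = settings.polish_maxiter * min(len(free) + 1, 10) // 10
        for rnd in range(settings.polish_rounds):
            rnd_seed = int(rng.integers(1, 2**31 - 1))
            reps = settings.n_reps * (2**rnd)
            maxiter = max(maxiter_base // (rnd + 1), 60)
            # smoothing counteracts low-replicate zero-cell bias; late
            # high-replicate rounds must maximize the exact objective or
            # they converge to the smoothed optimum instead
            smooth = _SEARCH_SMOOTH if rnd < settings.polish_rounds - 2 else 0.0
            p = _simplex_polish(
                observed, mid, p, free, bounds, reps, rnd_seed, maxiter, mu,
                smooth=smooth,
            )
        # score every restart's endpoint under one shared seed, one noise
        # doubling beyond the last polish round
        ll_final = _lncl(
            observed, mid, p,
            settings.n_reps * (2 ** max(settings.polish_rounds, 2)),
            final_seed,
        )
        if ll_final > best_ll:
            best_ll = ll_final
            best_p = p

    if best_p is None or not np.isfinite(best_ll):
        raise RuntimeError("optimization failed: no finite composite likelihood found")
    if settings.refine_epoch and mid == "changing_migration":
        best_p, best_ll = _refine_epoch(
            observed, best_p, best_ll, bounds, settings, final_seed, mu, rng
        )
    k = N_FREE_PARAMS[mid]
    return FitResult(
        model_id=mid,
        params=best_p,
        log_composite_likelihood=float(best_ll),
        n_free_params=k,
        aic=2.0 * k - 2.0 * float(best_ll),
        observed_fingerprint=_fingerprint(observed),
    )


def _refine_epoch(
    observed: Sfs2D,
    p: DemographicParams,
    ll: float,
    bounds: dict[str, tuple[float, float]],
    settings: FitSettings,
    final_seed: int,
    mu: float,
    rng: np.random.Generator,
) -> tuple[DemographicParams, float]:
    """Profile the epoch-switch time: from the incumbent optimum, re-optimize
    only the recent-epoch block (T2, M2 rates) at a grid of switch times and
    keep the best exact-scored point."""
    score_reps = settings.n_reps * (2 ** max(settings.polish_rounds, 2))
    refine_reps = settings.n_reps * 4
    free = list(_free_names("changing_migration"))

    def clip(name: str, v: float) -> float:
        lo, hi = bounds[name]
        return float(min(max(v, lo), hi))

    candidates = np.geomspace(
        max(p.t1 / 200.0, bounds["t2"][0]), p.t1 / 2.0, 8
    )
    best_p, best_ll = p, ll
    for t2 in candidates:
        if p.t2 > 0 and abs(np.log(t2 / p.t2)) < 0.25:
            continue  # already explored by the incumbent
        t2 = float(min(t2, p.t1))
        start = replace(p, t2=t2)
        if p.t2 > 0:
            # warm-start along the T2*M2 ridge: a shorter recent epoch needs
            # proportionally stronger recent gene flow, and vice versa
            scale = p.t2 / t2
            start = replace(
                start,
                m2_wd=clip("m2_wd", p.m2_wd * scale),
                m2_dw=clip("m2_dw", p.m2_dw * scale),
            )
        seed = int(rng.integers(1, 2**31 - 1))
        cand = _simplex_polish(
            observed, "changing_migration", start, free, bounds,
            refine_reps, seed, 130, mu, smooth=0.0,
        )
        cand_ll = _lncl(observed, "changing_migration", cand, score_reps, final_seed)
        if cand_ll > best_ll:
            best_p, best_ll = cand, cand_ll
    # settle the winner with one more exact pass before accepting it
    seed = int(rng.integers(1, 2**31 - 1))
    settled = _simplex_polish(
        observed, "changing_migration", best_p, free, bounds,
        refine_reps, seed, 100, mu, smooth=0.0,
    )
    settled_ll = _lncl(observed, "changing_migration", settled, score_reps, final_seed)
    if settled_ll > best_ll:
        best_p, best_ll = settled, settled_ll
    return best_p, best_ll


def _simplex_polish(
    observed: Sfs2D,
    model_id: str,
    p: DemographicParams,
    free: list[str],
    bounds: dict[str, tuple[float, float]],
    n_reps: int,
    seed: int,
    maxiter: int,
    mu: float,
    smooth: float = _SEARCH_SMOOTH,
) -> DemographicParams:
    """Nelder–Mead over the free parameters in log space, with one shared
    coalescent seed so the objective is deterministic within the round."""
    from scipy.optimize import minimize

    def p_from_x(x: np.ndarray) -> DemographicParams:
        vals = {n: float(np.exp(v)) for n, v in zip(free, x)}
        for n in free:
            lo, hi = bounds[n]
            vals[n] = min(max(vals[n], lo), hi)
        if "t2" in vals:
            vals["t2"] = min(vals["t2"], vals.get("t1", p.t1))
        full = {
            "anc_size": p.anc_size,
            "t1": p.t1,
            "n_wild": p.n_wild,
            "n_dom": p.n_dom,
            "m1_wd": p.m1_wd,
            "m1_dw": p.m1_dw,
            "t2": p.t2,
            "m2_wd": p.m2_wd,
            "m2_dw": p.m2_dw,
        }
        full.update(vals)
        out = DemographicParams(**full, mu=mu)
        if model_id == "constant_migration":
            out = _tie_constant_migration(out)
        if model_id == "no_migration":
            out = replace(out, m1_wd=0.0, m1_dw=0.0, m2_wd=0.0, m2_dw=0.0, t2=0.0)
        return out

    def objective(x: np.ndarray) -> float:
        return -_lncl(observed, model_id, p_from_x(x), n_reps, seed, smooth=smooth)

    x0 = np.log([max(float(getattr(p, n)), 1e-12) for n in free])
    # wide initial simplex (factor ~1.6 per axis in parameter space) so the
    # search can leave a mediocre start; NM shrinks it as it converges
    simplex = np.vstack([x0] + [x0 + 0.5 * np.eye(len(free))[i] for i in range(len(free))])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "xatol": 1e-3,
            "fatol": 0.25,
            "adaptive": True,
            "initial_simplex": simplex,
        },
    )
    return p_from_x(res.x)


def _warm_candidates(
    model_id: str, parent: DemographicParams, bounds: dict[str, tuple[float, float]]
) -> list[DemographicParams]:
    """Starts for a richer model derived from the nested simpler model's fit."""

    def clip(name: str, v: float) -> float:
        lo, hi = bounds[name]
        return float(min(max(v, lo), hi))

    out: list[DemographicParams] = []
    if model_id == "constant_migration":
        for m in (1e-5, 1e-4, 5e-4, 2e-3):
            out.append(
                replace(
                    parent,
                    m1_wd=clip("m1_wd", m),
                    m1_dw=clip("m1_dw", m),
                    m2_wd=clip("m2_wd", m),
                    m2_dw=clip("m2_dw", m),
                    t2=0.0,
                )
            )
    else:  # changing_migration: grid the epoch switch and the rate contrast
        if parent.m1_wd > 0 or parent.m1_dw > 0:
            m1_opts = [(max(parent.m1_wd, 1e-6), max(parent.m1_dw, 1e-6))]
            t1_scales = (1.0,)
        else:
            # a no-gene-flow parent absorbs migration into a shorter split,
            # so seed baseline rates and longer T1 as well
            m1_opts = [(1e-4, 1e-4), (6e-4, 6e-4)]
            t1_scales = (1.0, 3.0, 8.0)
        t1_lo, t1_hi = bounds["t1"]
        # anchor on the parent's split time but also span the search box:
        # a migration-free parent can collapse T1 by orders of magnitude
        t1_opts = sorted(
            {clip("t1", s * parent.t1) for s in t1_scales}
            | set(np.geomspace(4 * t1_lo, t1_hi / 4, 4).tolist())
        )
        for t1 in t1_opts:
            for m1_wd, m1_dw in m1_opts:
                for frac in (0.03, 0.1, 0.4):
                    t2 = min(clip("t2", frac * t1), t1)
                    for scale in (0.5, 4.0):
                        out.append(
                            replace(
                                parent,
                                t1=t1,
                                m1_wd=clip("m1_wd", m1_wd),
                                m1_dw=clip("m1_dw", m1_dw),
                                t2=t2,
                                m2_wd=clip("m2_wd", scale * m1_wd),
                                m2_dw=clip("m2_dw", scale * m1_dw),
                            )
                        )
    return out


def _line_search(
    observed: Sfs2D,
    model_id: str,
    p: DemographicParams,
    name: str,
    ll_current: float,
    bounds: dict[str, tuple[float, float]],
    span: float,
    n_reps: int,
    seed: int,
) -> tuple[DemographicParams, float]:
    lo, hi = bounds[name]
    if name == "t2":
        hi = min(hi, p.t1)
    current = float(getattr(p, name))
    current = min(max(current, lo), hi)

    def ll_at(value: float) -> float:
        return _lncl(observed, model_id, _apply(p, name, value, model_id), n_reps, seed,
                     smooth=_SEARCH_SMOOTH)

    # coarse geometric sweep around the current value, then one refinement
    best_v, best_ll = current, ll_current
    for stage_span, n_pts in ((span, 7), (span**0.25, 5)):
        grid = np.geomspace(
            max(best_v / stage_span, lo), min(best_v * stage_span, hi), n_pts
        )
        for v in grid:
            ll = ll_at(float(v))
            if ll > best_ll:
                best_ll, best_v = ll, float(v)
    return _apply(p, name, best_v, model_id), best_ll


def model_select(
    observed: Sfs2D,
    model_ids: tuple[str, ...] = MODEL_IDS,
    settings: FitSettings | None = None,
    seed: int = 0,
    mu: float = DEFAULT_MU,
    rescore_reps: int | None = None,
) -> list[FitResult]:
    """Fit candidate models and attach Akaike weights.

    Nested models warm-start richer ones. Before computing AIC, every fit's
    composite likelihood is re-evaluated under one shared coalescent seed at
    ``rescore_reps`` (default 4x the fitting replicates), so model
    comparisons are not confounded by independent Monte-Carlo noise.
    """
    settings = settings or FitSettings()
    mids = [canonical_model_id(m) for m in model_ids]
    fits: list[FitResult] = []
    parent: FitResult | None = None
    for i, mid in enumerate(mids):
        fit = fit_sfs(
            observed,
            mid,
            settings=settings,
            seed=seed + 13 * i,
            mu=mu,
            warm_start=parent is None,
            parent_params=parent.params if parent is not None else None,
        )
        fits.append(fit)
        parent = fit
    rescore_seed = int(np.random.default_rng(seed + 997).integers(1, 2**31 - 1))
    reps = rescore_reps or 4 * settings.n_reps
    for i, fit in enumerate(fits):
        # the models are nested in MODEL_IDS order: a simpler model's optimum
        # embeds as a valid parameter vector of every richer model, so the
        # richer fit can never legitimately score below it
        candidates = [fit.params]
        for prev in fits[:i]:
            emb = prev.params
            if fit.model_id == "constant_migration":
                emb = _tie_constant_migration(emb)
            candidates.append(emb)
        lls = [_lncl(observed, fit.model_id, c, reps, rescore_seed) for c in candidates]
        j = int(np.argmax(lls))
        fit.params = candidates[j]
        fit.log_composite_likelihood = float(lls[j])
        fit.aic = 2.0 * fit.n_free_params - 2.0 * float(lls[j])
    return akaike_weights(fits)


def akaike_weights(fits: list[FitResult]) -> list[FitResult]:
    """Attach Akaike weights w_i = exp(-dAIC_i/2)/sum_j exp(-dAIC_j/2)."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    fps = {f.observed_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("fits were computed on different observed spectra")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    return fits


def parametric_bootstrap(
    fit: FitResult,
    observed: Sfs2D,
    b: int = 100,
    settings: FitSettings | None = None,
    seed: int = 0,
    max_failure_fraction: float = 0.20,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% CIs from refits of spectra simulated at the MLE.

    Full-scale practice is 100 bootstrap spectra with 50 independent runs
    each; the ``settings`` argument scales that down. Fewer than 20
    replicates cannot support 2.5/97.5 percentiles and is rejected.
    """
    if b < 20:
        raise ValueError("parametric bootstrap needs at least 20 replicates")
    settings = settings or FitSettings(n_reps=2000, n_cycles=5, n_restarts=2)
    rng = np.random.default_rng(seed)
    names = [n for n in DEFAULT_BOUNDS if n in _free_names(fit.model_id)]
    estimates: dict[str, list[float]] = {n: [] for n in names}
    failures = 0
    model = build_model(fit.model_id, fit.params)
    for rep in range(b):
        rep_seed = int(rng.integers(1, 2**31 - 1))
        boot = simulate_sfs(
            model,
            n_sites=int(round(observed.total_sites)),
            n_wild_chroms=observed.n1,
            n_dom_chroms=observed.n2,
            mu=fit.params.mu,
            n_reps=max(settings.n_reps, 2000),
            seed=rep_seed,
            mode="sampled",
            folded=observed.folded,
        )
        try:
            refit = fit_sfs(
                boot,
                fit.model_id,
                settings=settings,
                seed=rep_seed,
                mu=fit.params.mu,
                start=fit.params,
            )
        except RuntimeError:
            failures += 1
            continue
        for n in names:
            estimates[n].append(float(getattr(refit.params, n)))
    if failures > max_failure_fraction * b:
        raise RuntimeError(f"too many bootstrap refit failures ({failures}/{b})")
    ci = {
        n: (
            float(np.percentile(v, 2.5)),
            float(np.percentile(v, 97.5)),
        )
        for n, v in estimates.items()
        if v
    }
    fit.bootstrap_ci = ci
    return ci


def _free_names(model_id: str) -> tuple[str, ...]:
    if model_id == "no_migration":
        return ("anc_size", "t1", "n_wild", "n_dom")
    if model_id == "constant_migration":
        return ("anc_size", "t1", "n_wild", "n_dom", "m1_wd", "m1_dw")
    return (
        "anc_size",
        "t1",
        "n_wild",
        "n_dom",
        "m1_wd",
        "m1_dw",
        "t2",
        "m2_wd",
        "m2_dw",
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def migrants_per_generation(n: float, m: float, ndigits: int | None = 2) -> float:
    """Expected migrants per generation, N_e * m (reported to 2 decimals)."""
    if n < 0:
        raise ValueError("N must be >= 0")
    if not 0.0 <= m < 1.0:
        raise ValueError("m must be in [0, 1)")
    value = n * m
    return round(value, ndigits) if ndigits is not None else value


@dataclass(frozen=True)
class CalendarDate:
    years_before_present: float
    calendar_year: float  # negative means BCE
    is_bce: bool

    @property
    def years_bp_nearest_decade(self) -> int:
        return int(round(self.years_before_present / 10.0)) * 10

    @property
    def calendar_nearest_millennium(self) -> int:
        """Magnitude of the calendar year rounded to the nearest millennium
        (report as BCE when ``is_bce``)."""
        return int(round(abs(self.calendar_year) / 1000.0)) * 1000


def generations_to_calendar(
    generations: float,
    generation_time_years: float = DEFAULT_GENERATION_TIME,
    present_year: int = 2020,
) -> CalendarDate:
    """Convert a generations-before-present age to calendar time."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    years = generations * generation_time_years
    calendar = present_year - years
    return CalendarDate(
        years_before_present=years,
        calendar_year=calendar,
        is_bce=calendar < 0,
    )
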