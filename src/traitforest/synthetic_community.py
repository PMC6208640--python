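"""Toy metabolic communities with known interaction mechanisms.

Two generators make the whole pipeline testable end to end without external
genome-scale models:

* a well-mixed **batch dynamic-FBA simulator** over small linear-pathway
  stoichiometric models.  Each organism converts one growth substrate into
  biomass (optionally secreting a by-product; optionally consuming a
  partner's by-product), and may carry "decoy" uptake exchanges that are
  present in its trait vector but lead nowhere metabolically.  Competition
  and cross-feeding are *emergent*: they arise from two organisms drawing on
  or feeding the same external metabolite pool, and the ground-truth
  mechanism sets are read off the simulated exchange fluxes — never from the
  construction — so they are an independent check on the trait-based
  predictions.

* a rule-based **auxotroph community generator** emulating engineered
  amino-acid auxotroph panels: every strain lacks one biosynthesis
  capability, and its coculture fold change is high when the partner can
  supply the missing amino acid.

Flux sign convention: exchange flux < 0 is uptake, > 0 is secretion.  The
environment is updated with forward-Euler bookkeeping (``amount += flux *
biomass * dt``) so mass conservation is exact up to rounding and testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .traitspace import InteractionTable, TraitMatrix

__all__ = [
    "ToyModel",
    "BatchEnvironment",
    "RunResult",
    "MechanismTruth",
    "CampaignResult",
    "linear_pathway_model",
    "fba_solve",
    "dfba_run",
    "pairwise_campaign",
    "generate_community",
    "traits_from_models",
    "generate_auxotroph_community",
    "competition_candidate_map",
    "facilitation_candidate_map",
]

#: a flux event counts toward a mechanism truth set only if it moves more
#: than this much mass (mmol) in one step — guards against LP float noise
MECHANISM_FLUX_EPS = 1e-9

GROWTH_EPS = 1e-9


@dataclass(frozen=True)
class ToyModel:
    """Small stoichiometric model with explicit exchange reactions.

    ``S`` is metabolites x reactions; each exchange reaction column touches
    exactly one (external) metabolite with coefficient -1, so a positive
    exchange flux exports the metabolite to the environment and a negative
    one imports it.  Bounds are mmol per gDW per hour.
    """

    model_id: str
    metabolites: tuple[str, ...]
    reactions: tuple[str, ...]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    exchanges: dict  # external metabolite name -> reaction index
    biomass_index: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.shape != (len(self.metabolites), len(self.reactions)):
            raise ValueError("S shape does not match metabolite/reaction lists")
        for met, rxn in self.exchanges.items():
            col = S[:, rxn]
            touched = np.nonzero(col)[0]
            if len(touched) != 1 or self.metabolites[touched[0]] != met:
                raise ValueError(
                    f"exchange reaction {self.reactions[rxn]!r} must touch exactly "
                    f"the external metabolite {met!r}")
        if self.ub[self.biomass_index] < 0:
            raise ValueError("biomass reaction upper bound must be >= 0")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "lb", np.asarray(self.lb, dtype=float))
        object.__setattr__(self, "ub", np.asarray(self.ub, dtype=float))

    def can_uptake(self, met: str) -> bool:
        return met in self.exchanges and self.lb[self.exchanges[met]] < 0

    def can_secrete(self, met: str) -> bool:
        return met in self.exchanges and self.ub[self.exchanges[met]] > 0

    def to_dict(self) -> dict:
        rows, cols = np.nonzero(self.S)
        return {
            "model_id": self.model_id,
            "metabolites": list(self.metabolites),
            "reactions": list(self.reactions),
            "S_triplets": [[int(r), int(c), float(self.S[r, c])]
                           for r, c in zip(rows, cols)],
            "lb": [None if np.isinf(v) else float(v) for v in self.lb],
            "ub": [None if np.isinf(v) else float(v) for v in self.ub],
            "exchanges": {m: int(i) for m, i in self.exchanges.items()},
            "biomass_index": int(self.biomass_index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToyModel":
        S = np.zeros((len(d["metabolites"]), len(d["reactions"])))
        for r, c, v in d["S_triplets"]:
            S[r, c] = v
        lb = np.array([-np.inf if v is None else v for v in d["lb"]])
        ub = np.array([np.inf if v is None else v for v in d["ub"]])
        return cls(d["model_id"], tuple(d["metabolites"]), tuple(d["reactions"]),
                   S, lb, ub, dict(d["exchanges"]), d["biomass_index"])


def linear_pathway_model(model_id: str, substrates: dict, vmax: float = 10.0,
                         byproducts: dict | None = None,
                         decoys: tuple = ()) -> ToyModel:
    """Build a linear-pathway toy model.

    ``substrates`` maps external metabolite -> biomass yield (gDW/mmol).
    ``byproducts`` maps a substrate -> ``(byproduct_metabolite, gamma)``:
    consuming one mmol of that substrate co-produces ``gamma`` mmol of the
    by-product, which the model can only secrete.  ``decoys`` are external
    metabolites with an uptake-capable exchange but no connected pathway,
    so steady state forces their flux to zero.
    """
    byproducts = byproducts or {}
    mets: list[str] = []
    for s in substrates:
        mets.append(s)
    for s, (b, _g) in byproducts.items():
        if s not in substrates:
            raise ValueError(f"by-product source {s!r} is not a substrate")
        if b not in mets:
            mets.append(b)
    for d in decoys:
        if d in mets:
            raise ValueError(f"decoy {d!r} collides with a pathway metabolite")
        mets.append(d)
    mets.append("biomass_pre")
    m_idx = {m: k for k, m in enumerate(mets)}
    pre = m_idx["biomass_pre"]

    reactions: list[str] = []
    cols: list[np.ndarray] = []
    lb: list[float] = []
    ub: list[float] = []
    exchanges: dict[str, int] = {}

    def add(name, coeffs, lo, hi):
        col = np.zeros(len(mets))
        for m, v in coeffs.items():
            col[m_idx[m]] = v
        reactions.append(name)
        cols.append(col)
        lb.append(lo)
        ub.append(hi)
        return len(reactions) - 1

    for s, y in substrates.items():
        exchanges[s] = add(f"EX_{s}", {s: -1.0}, -vmax, 0.0)
        coeffs = {s: -1.0, "biomass_pre": y}
        if s in byproducts:
            b, g = byproducts[s]
            coeffs[b] = g
        add(f"CONV_{s}", coeffs, 0.0, np.inf)
    for s, (b, _g) in byproducts.items():
        if b not in exchanges:
            exchanges[b] = add(f"EX_{b}", {b: -1.0}, 0.0, np.inf)
    for d in decoys:
        exchanges[d] = add(f"EX_{d}", {d: -1.0}, -vmax, 0.0)
    biomass = add("BIOMASS", {"biomass_pre": -1.0}, 0.0, np.inf)

    return ToyModel(model_id, tuple(mets), tuple(reactions),
                    np.column_stack(cols), np.array(lb), np.array(ub),
                    exchanges, biomass)


@dataclass(frozen=True)
class FBAResult:
    fluxes: np.ndarray
    growth: float


def fba_solve(model: ToyModel, uptake_caps: dict | None = None) -> FBAResult:
    """Maximize the biomass flux subject to ``S v = 0`` and flux bounds.

    ``uptake_caps`` maps external metabolite -> maximum uptake rate
    (mmol/gDW/h); it can only tighten the model's own exchange bounds.
    """
    lb = model.lb.copy()
    if uptake_caps:
        for met, cap in uptake_caps.items():
            if met in model.exchanges:
                rxn = model.exchanges[met]
                lb[rxn] = max(lb[rxn], -max(cap, 0.0))
    if np.any(lb > model.ub + 1e-12):
        raise ValueError("inconsistent bounds: lb > ub")
    c = np.zeros(len(model.reactions))
    c[model.biomass_index] = -1.0
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(len(model.metabolites)),
                  bounds=list(zip(lb, model.ub)), method="highs")
    if not res.success:
        raise RuntimeError(f"FBA infeasible for {model.model_id}: {res.message}")
    return FBAResult(res.x, float(res.x[model.biomass_index]))


@dataclass(frozen=True)
class BatchEnvironment:
    """Well-mixed batch culture: a finite pool of external metabolites.

    ``dt`` in hours, amounts in mmol, biomass in gDW.
    """

    metabolites: tuple[str, ...]
    amounts: np.ndarray
    dt: float = 0.1
    n_steps: int = 240
    initial_biomass: float = 0.01

    def __post_init__(self) -> None:
        amounts = np.asarray(self.amounts, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(amounts < 0):
            raise ValueError("metabolite amounts must be non-negative")
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "amounts", amounts)


@dataclass
class RunResult:
    """One batch run: biomass trajectories and signed metabolite transfers.

    ``transfers[t, o, m]`` is the mmol moved by organism ``o`` for
    metabolite ``m`` at step ``t`` (negative = taken up from, positive =
    secreted into the environment).
    """

    model_ids: tuple[str, ...]
    biomass: np.ndarray          # (steps_run + 1, n_org)
    transfers: np.ndarray        # (steps_run, n_org, n_env_metabolites)
    amounts_initial: np.ndarray
    amounts_final: np.ndarray
    steps_run: int

    @property
    def final_biomass(self) -> np.ndarray:
        return self.biomass[-1]

    def mass_balance_residual(self) -> np.ndarray:
        """Per-metabolite violation of the Euler bookkeeping identity."""
        return self.amounts_final - (self.amounts_initial
                                     + self.transfers.sum(axis=(0, 1)))

    def uptake_events(self, org: int) -> np.ndarray:
        return self.transfers[:, org, :] < -MECHANISM_FLUX_EPS

    def secretion_events(self, org: int) -> np.ndarray:
        return self.transfers[:, org, :] > MECHANISM_FLUX_EPS


def dfba_run(models, env: BatchEnvironment, initial_biomass=None,
             sharing: str = "proportional") -> RunResult:
    """Discretized batch coculture of one or two (or more) toy models.

    Per step, each organism's uptake of metabolite ``m`` is capped at
    ``min(Vmax, amount_m / (demanding_biomass * dt))`` — with proportional
    sharing, a scarce pool is split among demanders in proportion to their
    biomass; with ``sharing="sequential"`` organisms draw in list order.
    Each organism then solves its FBA problem, biomass grows by forward
    Euler (``B <- B * (1 + mu * dt)``), and the pools are updated with the
    realized exchange fluxes.  The run stops after ``n_steps`` or as soon
    as every growth rate falls below 1e-9/h.
    """
    if sharing not in ("proportional", "sequential"):
        raise ValueError(f"unknown sharing rule {sharing!r}")
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    n_org = len(models)
    m_idx = {m: k for k, m in enumerate(env.metabolites)}
    for mod in models:
        unknown = set(mod.exchanges) - set(env.metabolites)
        if unknown:
            raise ValueError(
                f"{mod.model_id} exchanges metabolites absent from the "
                f"environment: {sorted(unknown)}")
    if initial_biomass is None:
        B = np.full(n_org, env.initial_biomass, dtype=float)
    else:
        B = np.asarray(initial_biomass, dtype=float).copy()
    amounts = env.amounts.copy()
    dt = env.dt

    uptake_mets = [[m for m in mod.exchanges if mod.can_uptake(m)] for mod in models]
    biomass_traj = [B.copy()]
    transfers = []
    steps = 0
    # the LP depends only on the effective caps min(Vmax, share); during the
    # Vmax-limited growth phase these repeat step after step, so caching the
    # last solution per organism avoids re-solving an identical LP
    lp_cache: list[tuple] = [(None, None)] * n_org
    for _ in range(env.n_steps):
        step_transfer = np.zeros((n_org, len(env.metabolites)))
        mus = np.zeros(n_org)
        if sharing == "proportional":
            demand = np.zeros(len(env.metabolites))
            for o, mod in enumerate(models):
                if B[o] <= 0:
                    continue
                for m in uptake_mets[o]:
                    demand[m_idx[m]] += B[o]
        remaining = amounts.copy()
        for o, mod in enumerate(models):
            caps = {}
            for m in uptake_mets[o]:
                k = m_idx[m]
                if sharing == "proportional":
                    share = remaining[k] / (demand[k] * dt) if demand[k] > 0 else 0.0
                else:
                    share = remaining[k] / (B[o] * dt) if B[o] > 0 else 0.0
                caps[m] = share
            key = tuple(min(-mod.lb[mod.exchanges[m]], caps[m])
                        for m in uptake_mets[o])
            if lp_cache[o][0] == key:
                sol = lp_cache[o][1]
            else:
                sol = fba_solve(mod, caps)
                lp_cache[o] = (key, sol)
            mus[o] = sol.growth
            for m, rxn in mod.exchanges.items():
                moved = sol.fluxes[rxn] * B[o] * dt
                step_transfer[o, m_idx[m]] = moved
                if sharing == "sequential" and moved < 0:
                    remaining[m_idx[m]] = max(0.0, remaining[m_idx[m]] + moved)
        amounts = amounts + step_transfer.sum(axis=0)
        low = amounts.min()
        if low < -1e-9:
            raise RuntimeError(
                f"environment bookkeeping went negative ({low:.3e} mmol)")
        np.clip(amounts, 0.0, None, out=amounts)
        B = B * (1.0 + mus * dt)
        transfers.append(step_transfer)
        biomass_traj.append(B.copy())
        steps += 1
        if np.all(mus < GROWTH_EPS):
            break
    return RunResult(tuple(m.model_id for m in models), np.asarray(biomass_traj),
                     np.asarray(transfers) if transfers else
                     np.zeros((0, n_org, len(env.metabolites))),
                     env.amounts.copy(), amounts, steps)


@dataclass(frozen=True)
class MechanismTruth:
    """Flux-derived ground truth per ordered pair.

    ``contended[(i, j)]``: metabolites both organisms took up in the same
    coculture step.  ``facilitation[(i, j)]``: metabolites partner ``j``
    secreted and responder ``i`` took up in the same step.
    """

    contended: dict
    facilitation: dict

    def contended_for(self, i: str, j: str) -> frozenset:
        return self.contended.get((i, j), frozenset())

    def facilitation_for(self, i: str, j: str) -> frozenset:
        return self.facilitation.get((i, j), frozenset())


def _pair_truth(run: RunResult, env: BatchEnvironment):
    """Mechanism sets of a two-organism run, read off the flux series."""
    up0 = run.uptake_events(0)
    up1 = run.uptake_events(1)
    sec0 = run.secretion_events(0)
    sec1 = run.secretion_events(1)
    mets = np.asarray(env.metabolites)
    contended = frozenset(str(m) for m in mets[np.any(up0 & up1, axis=0)])
    fac_01 = frozenset(str(m) for m in mets[np.any(up0 & sec1, axis=0)])  # 0 fed by 1
    fac_10 = frozenset(str(m) for m in mets[np.any(up1 & sec0, axis=0)])
    return contended, fac_01, fac_10


@dataclass
class CampaignResult:
    """All monoculture and pairwise coculture runs of a community."""

    table: InteractionTable       # diagonal = B_ii, off-diagonal = X_ij
    truth: MechanismTruth
    mono_runs: dict               # organism id -> RunResult
    co_runs: dict                 # frozenset({i, j}) -> RunResult
    models: list

    def all_runs(self):
        yield from self.mono_runs.values()
        yield from self.co_runs.values()


def pairwise_campaign(models, env: BatchEnvironment,
                      sharing: str = "proportional") -> CampaignResult:
    """Run N monocultures and C(N,2) cocultures from the same initial medium.

    Produces the relative-yield matrix ``X`` (ordered responses, diagonal
    holding the monoculture biomass ``B_ii``) and the flux-derived mechanism
    truth.  Organisms whose monoculture fails to grow get NA responses.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("a pairwise campaign needs at least two organisms")
    ids = [m.model_id for m in models]
    mono: dict[str, RunResult] = {}
    b_mono = np.empty(len(models))
    grew = np.empty(len(models), dtype=bool)
    for k, mod in enumerate(models):
        run = dfba_run([mod], env, sharing=sharing)
        mono[mod.model_id] = run
        b_mono[k] = run.final_biomass[0]
        grew[k] = b_mono[k] > env.initial_biomass * (1.0 + GROWTH_EPS)
    X = np.full((len(models), len(models)), np.nan)
    np.fill_diagonal(X, b_mono)
    contended: dict = {}
    facilitation: dict = {}
    co: dict = {}
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            run = dfba_run([models[a], models[b]], env, sharing=sharing)
            co[frozenset((ids[a], ids[b]))] = run
            if grew[a]:
                X[a, b] = (run.final_biomass[0] - b_mono[a]) / b_mono[a]
            if grew[b]:
                X[b, a] = (run.final_biomass[1] - b_mono[b]) / b_mono[b]
            cont, fac_ab, fac_ba = _pair_truth(run, env)
            if cont:
                contended[(ids[a], ids[b])] = cont
                contended[(ids[b], ids[a])] = cont
            if fac_ab:
                facilitation[(ids[a], ids[b])] = fac_ab
            if fac_ba:
                facilitation[(ids[b], ids[a])] = fac_ba
    table = InteractionTable(tuple(ids), X, "relative_yield")
    return CampaignResult(table, MechanismTruth(contended, facilitation),
                          mono, co, models)


# ---------------------------------------------------------------------------
# community generators

SCENARIOS = ("single_competition", "cross_feeding", "mixed")


@dataclass(frozen=True)
class CommunityDesign:
    """Planted design notes of a generated community (for inspection only;
    evaluation uses the flux-derived truth, not these notes)."""

    scenario: str
    seed: int
    substrate_of: dict        # organism -> growth substrate metabolite
    groups: tuple             # tuples of organism ids sharing one substrate
    chains: tuple             # (producer, consumer, byproduct) triples
    decoys_of: dict


def generate_community(n_organisms: int, n_metabolites: int,
                       scenario: str = "single_competition", seed: int = 0,
                       group_size: int = 4, n_decoys: int = 6,
                       supply: float = 10.0, vmax: float = 10.0,
                       dt: float = 0.1, n_steps: int = 240,
                       initial_biomass: float = 0.01,
                       byproduct_gamma: float = 0.5,
                       n_byproducts: int = 2):
    """Generate toy models plus a shared batch environment.

    ``single_competition``: organisms are grouped ``group_size`` at a time
    onto a shared growth substrate (leftovers get private substrates), so a
    pair either competes over exactly one metabolite or not at all.
    ``cross_feeding`` plants producer -> consumer by-product chains on top
    of private substrates.  ``mixed`` does both.  Every organism additionally
    draws ``n_decoys`` decoy uptake exchanges from the unused metabolite
    pool, which blur trait-similarity baselines without altering the flux
    dynamics.  Biomass yields vary per organism (uniform 0.08-0.12
    gDW/mmol).  Fully reproducible given ``seed``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if scenario == "single_competition" and n_metabolites < n_organisms:
        raise ValueError("single_competition needs n_metabolites >= n_organisms")
    if n_organisms < 2:
        raise ValueError("need at least two organisms")
    rng = np.random.default_rng(seed)
    mets = tuple(f"met{k:03d}" for k in range(n_metabolites))
    org_ids = tuple(f"org{k:02d}" for k in range(n_organisms))
    pool = [str(m) for m in rng.permutation(mets)]

    substrate_of: dict[str, str] = {}
    groups: list[tuple[str, ...]] = []
    chains: list[tuple[str, str, str]] = []

    if scenario in ("single_competition", "mixed"):
        n_grouped = n_organisms if scenario == "single_competition" else \
            max(group_size, int(0.6 * n_organisms) // group_size * group_size)
        n_groups = n_grouped // group_size
        grouped = list(org_ids[:n_groups * group_size])
        for g in range(n_groups):
            s = pool.pop()
            members = grouped[g * group_size:(g + 1) * group_size]
            groups.append(tuple(members))
            for o in members:
                substrate_of[o] = s
    for o in org_ids:
        if o not in substrate_of:
            substrate_of[o] = pool.pop()

    byproducts_of: dict[str, dict] = {o: {} for o in org_ids}
    consumes_by: dict[str, dict] = {o: {} for o in org_ids}
    if scenario in ("cross_feeding", "mixed"):
        free = [o for o in org_ids if all(o not in g for g in groups)]
        n_chains = max(1, len(free) // 2)
        # chains reuse a small pool of by-products (think common
        # fermentation products) so the secretion/uptake traits generalize
        # across pairs instead of being unique to one chain
        bpool = [pool.pop() for _ in range(min(n_byproducts, max(1, len(pool))))]
        for k in range(n_chains):
            if 2 * k + 1 >= len(free):
                break
            producer, consumer = free[2 * k], free[2 * k + 1]
            b = bpool[k % len(bpool)]
            byproducts_of[producer] = {substrate_of[producer]: (b, byproduct_gamma)}
            consumes_by[consumer] = {b: None}  # yield filled below
            chains.append((producer, consumer, b))

    used = set(substrate_of.values())
    for o in org_ids:
        for sub in byproducts_of[o].values():
            used.add(sub[0])
    decoy_pool = [m for m in mets if m not in used]

    models = []
    decoys_of: dict[str, tuple] = {}
    for o in org_ids:
        y = float(rng.uniform(0.08, 0.12))
        substrates = {substrate_of[o]: y}
        for b in consumes_by[o]:
            substrates[b] = y
        k = min(n_decoys, len(decoy_pool))
        decoys = tuple(
            str(d) for d in rng.choice(decoy_pool, size=k, replace=False)) if k else ()
        decoys_of[o] = decoys
        models.append(linear_pathway_model(
            o, substrates, vmax=vmax, byproducts=byproducts_of[o] or None,
            decoys=decoys))

    byproduct_mets = {b for _p, _c, b in chains}
    amounts = np.array([0.0 if m in byproduct_mets else supply for m in mets])
    env = BatchEnvironment(mets, amounts, dt=dt, n_steps=n_steps,
                           initial_biomass=initial_biomass)
    design = CommunityDesign(scenario, seed, substrate_of, tuple(groups),
                             tuple(chains), decoys_of)
    return models, env, design


def traits_from_models(models, metabolite_universe=None) -> TraitMatrix:
    """Presence/absence exchange traits: one uptake and one secretion feature
    per external metabolite, set to 1 iff the model's exchange bounds permit
    that direction.  Traits are purely structural — they never depend on
    simulated fluxes.
    """
    models = list(models)
    if metabolite_universe is None:
        seen: list[str] = []
        for m in models:
            for met in m.exchanges:
                if met not in seen:
                    seen.append(met)
        metabolite_universe = seen
    mets = list(metabolite_universe)
    features = [f"uptake_{m}" for m in mets] + [f"secretion_{m}" for m in mets]
    values = np.zeros((len(models), len(features)), dtype=np.int8)
    for r, mod in enumerate(models):
        for k, met in enumerate(mets):
            if mod.can_uptake(met):
                values[r, k] = 1
            if mod.can_secrete(met):
                values[r, len(mets) + k] = 1
    return TraitMatrix(tuple(m.model_id for m in models), tuple(features), values)


def competition_candidate_map(metabolites, partner_suffix: str = "_p") -> dict:
    """Candidate metabolite -> (responder uptake feature, partner uptake
    feature); the mechanism of competition is shared uptake."""
    return {m: (f"uptake_{m}", f"uptake_{m}{partner_suffix}") for m in metabolites}


def facilitation_candidate_map(metabolites, partner_suffix: str = "_p") -> dict:
    """Candidate metabolite -> (responder uptake feature, partner secretion
    feature); the mechanism of cross-feeding is partner secretion consumed
    by the responder."""
    return {m: (f"uptake_{m}", f"secretion_{m}{partner_suffix}") for m in metabolites}


# ---------------------------------------------------------------------------
# rule-based auxotroph community

AMINO_ACIDS = ("arg", "cys", "gly", "his", "ile", "leu", "lys", "met",
               "phe", "pro", "ser", "thr", "trp", "tyr")


def generate_auxotroph_community(n_strains: int = 14, seed: int = 0,
                                 strong_mean: float = 8.0,
                                 weak_mean: float = 1.25,
                                 noise_sd: float = 0.3,
                                 aa_effect_sd: float = 0.6,
                                 n_knockouts: int | None = None):
    """Synthetic auxotroph panel: strains lacking one amino-acid biosynthesis.

    Each strain lacks exactly one biosynthetic capability (knockouts cycle
    through ``n_knockouts`` distinct amino acids, default half the panel, so
    same-knockout pairs exist and cannot rescue each other).  The coculture
    fold change of responder ``i`` with partner ``j`` is drawn log-normally
    around an amino-acid-specific rescue magnitude when ``j`` possesses
    ``i``'s missing capability and around ``weak_mean`` otherwise;
    ``noise_sd`` is the per-pair log-scale sd.  Rescue magnitudes vary by
    amino acid (log-normal spread ``aa_effect_sd`` around ``strong_mean``),
    emulating the unequal biosynthetic costs of different amino acids: which
    amino acid the *responder* is missing carries information beyond bare
    complementation, whereas almost any partner that has the capability can
    provide it.

    Returns ``(TraitMatrix, InteractionTable (fold_change mode), truths)``
    where ``truths[(i, j)]`` is the responder's missing amino acid — the
    trait whose presence in the partner decides the outcome.
    """
    if n_strains < 3:
        raise ValueError("need at least three strains")
    if n_strains > len(AMINO_ACIDS) ** 2:
        raise ValueError("too many strains for distinct labels")
    rng = np.random.default_rng(seed)
    if n_knockouts is None:
        n_knockouts = max(2, n_strains // 2)
    n_knockouts = min(n_knockouts, len(AMINO_ACIDS))
    strain_ids = tuple(f"strain{k:02d}" for k in range(n_strains))
    ko = [k % n_knockouts for k in range(n_strains)]
    features = tuple(f"biosynth_{aa}" for aa in AMINO_ACIDS)
    values = np.ones((n_strains, len(features)), dtype=np.int8)
    for s, k in enumerate(ko):
        values[s, k] = 0
    traits = TraitMatrix(strain_ids, features, values)

    rescue_mean = strong_mean * np.exp(
        aa_effect_sd * rng.standard_normal(len(AMINO_ACIDS)))
    fc = np.full((n_strains, n_strains), np.nan)
    truths: dict[tuple[str, str], frozenset] = {}
    for i in range(n_strains):
        for j in range(n_strains):
            if i == j:
                continue
            complement = values[j, ko[i]] == 1
            mean = rescue_mean[ko[i]] if complement else weak_mean
            fc[i, j] = float(np.exp(np.log(mean) + noise_sd * rng.standard_normal()))
            truths[(strain_ids[i], strain_ids[j])] = frozenset({AMINO_ACIDS[ko[i]]})
    table = InteractionTable(strain_ids, fc, "fold_change")
    return traits, table, truths


def auxotroph_candidate_map(partner_suffix: str = "_p") -> dict:
    return {aa: (f"biosynth_{aa}", f"biosynth_{aa}{partner_suffix}")
            for aa in AMINO_ACIDS}
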