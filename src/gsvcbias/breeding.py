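"""Forward simulation of the 35-year dairy breeding program.

Timeline (years relative to the start of recording):

* founders (unknown parents) are drawn from the historical population by one
  random-mating expansion generation; their TBV variance is the configured
  P-base truth;
* ``setup_years`` random-mating years (born years <= 0) provide the first
  replacement heifers;
* conventional phase, years 1..Y1: each year the herd is evaluated with
  pedigree BLUP (true variances), the top young bulls by parent average
  enter service for up to four years, the herd of ``n_cows`` is maintained
  by random culling, and every first-lactation cow gets one record
  y = HYS + TBV + e;
* genomic phase, years Y1+1..Y1+Y2: bull and heifer calves are pre-selected
  on PA for genotyping, and sires are the top genotyped bulls ranked on
  ssGBLUP GEBV.

All haplotypes are retained, so "true" genotypes of any cohort (e.g. the
G-base years) are available for allele-frequency bases even for animals
that were never genotyped in the program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genome import (
    GeneticMap,
    HaplotypePopulation,
    QtlEffectSet,
    assign_qtl_effects,
    make_gametes,
    run_historical,
    select_loci,
)
from .relationships import (
    a_inverse,
    a_submatrix,
    allele_frequencies,
    blend_g,
    center_markers,
    g_matrix,
    h_inverse,
)
from .reml import MixedModelSpec, hys_design, solve_blup

__all__ = [
    "PedigreeBook",
    "SchemeState",
    "make_founders",
    "run_conventional_phase",
    "run_gs_phase",
    "simulate",
    "true_vc",
]


@dataclass
class PedigreeBook:
    """Columnar animal records; index order is chronological (parents first)."""

    sire: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    dam: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    sex: np.ndarray = field(default_factory=lambda: np.zeros(0, np.uint8))  # 0 cow, 1 bull
    birth_year: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    is_genotyped: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    is_proven: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    tbv: np.ndarray = field(default_factory=lambda: np.zeros(0, float))

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def append(self, sire, dam, sex, birth_year, tbv) -> np.ndarray:
        k = len(sire)
        new = np.arange(self.n, self.n + k)
        self.sire = np.concatenate([self.sire, np.asarray(sire, np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, np.int64)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.uint8)])
        self.birth_year = np.concatenate(
            [self.birth_year, np.full(k, birth_year, np.int64)]
        )
        self.is_genotyped = np.concatenate([self.is_genotyped, np.zeros(k, bool)])
        self.is_proven = np.concatenate([self.is_proven, np.zeros(k, bool)])
        self.tbv = np.concatenate([self.tbv, np.asarray(tbv, float)])
        self.validate_parents(new)
        return new

    def validate_parents(self, idx) -> None:
        s, d = self.sire[idx], self.dam[idx]
        known_s, known_d = s[s >= 0], d[d >= 0]
        if np.any(self.sex[known_s] != 1) or np.any(self.sex[known_d] != 0):
            raise ValueError("sire must be male and dam female")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n) + 1,
                "sire": np.where(self.sire < 0, 0, self.sire + 1),
                "dam": np.where(self.dam < 0, 0, self.dam + 1),
                "birth_year": self.birth_year,
                "sex": self.sex,
            }
        )


def true_vc(tbv: np.ndarray, cohort: np.ndarray) -> float:
    """Empirical variance of true breeding values over a cohort (ddof=1)."""
    cohort = np.asarray(cohort)
    if cohort.dtype == bool:
        cohort = np.flatnonzero(cohort)
    if cohort.size < 2:
        raise ValueError("cohort must contain at least two animals")
    return float(np.var(np.asarray(tbv)[cohort], ddof=1))


@dataclass
class SchemeState:
    """Mutable simulation state; returned by the phase runners."""

    config: SimulationConfig
    gmap: GeneticMap
    effects: QtlEffectSet
    pedigree: PedigreeBook
    haplo: np.ndarray  # (n, 2, L) uint8, row-aligned with pedigree
    herd: np.ndarray  # pedigree indices of current cows
    herd_of: dict  # cow index -> herd id
    active_sires: list  # (pedigree index, year entered service)
    cohort_range: dict  # birth year -> (start, stop) pedigree indices
    hys_effects: dict  # (herd, year, season) -> effect
    rec_animal: list = field(default_factory=list)
    rec_value: list = field(default_factory=list)
    rec_herd: list = field(default_factory=list)
    rec_year: list = field(default_factory=list)
    rec_season: list = field(default_factory=list)
    year: int = 0
    eval_vc: tuple | None = None  # variances used inside evaluations (None = true)
    _seedseq: np.random.SeedSequence | None = None
    _rng: np.random.Generator | None = None
    p_base_freqs: np.ndarray | None = None

    @property
    def phenotypes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": np.asarray(self.rec_animal, np.int64),
                "value": np.asarray(self.rec_value, float),
                "herd": np.asarray(self.rec_herd, np.int64),
                "year": np.asarray(self.rec_year, np.int64),
                "season": np.asarray(self.rec_season, np.int64),
            }
        )

    def cohort(self, year: int) -> np.ndarray:
        lo, hi = self.cohort_range.get(year, (0, 0))
        return np.arange(lo, hi)

    def marker_genotypes(self, idx: np.ndarray) -> np.ndarray:
        g = self.haplo[idx].sum(axis=1, dtype=np.int16)
        return g[:, self.gmap.marker_idx]

    def genotyped_idx(self) -> np.ndarray:
        return np.flatnonzero(self.pedigree.is_genotyped)

    def g_base_cohort(self) -> np.ndarray:
        y1 = self.config.scheme.years_conventional
        by = self.pedigree.birth_year
        return np.flatnonzero((by >= y1 - 2) & (by <= y1))

    def _spawn_seed(self) -> int:
        return int(self._seedseq.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)


def make_founders(
    hist: HaplotypePopulation, effects_target: float, config: SimulationConfig, seed: int
):
    """Expand the historical population into the founder herd.

    Returns (state, effects).  Founder TBV variance equals the configured
    base genetic variance exactly (QTL effects rescaled on these animals).
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sch = config.scheme
    n_f = sch.n_cows + sch.n_founder_bulls
    nh = hist.n_individuals
    sires = rng.integers(0, nh, n_f)
    dams = (sires + 1 + rng.integers(0, nh - 1, n_f)) % nh
    seed_a = int(rng.integers(0, 2**31 - 1))
    seed_b = int(rng.integers(0, 2**31 - 1))
    gam_s = make_gametes(hist.haplo, sires, hist.gmap, seed_a)
    gam_d = make_gametes(hist.haplo, dams, hist.gmap, seed_b)
    haplo = np.stack([gam_s, gam_d], axis=1)
    founder_pop = HaplotypePopulation(haplo=haplo, gmap=hist.gmap)
    effects = assign_qtl_effects(founder_pop, effects_target, int(rng.integers(0, 2**31 - 1)))
    tbv = effects.breeding_values(founder_pop)

    ped = PedigreeBook()
    birth = -sch.setup_years
    sex = np.concatenate([np.zeros(sch.n_cows, np.uint8), np.ones(sch.n_founder_bulls, np.uint8)])
    ped.append(np.full(n_f, -1), np.full(n_f, -1), sex, birth, tbv)
    herd = np.arange(sch.n_cows)
    herd_of = {int(i): int(rng.integers(0, sch.n_herds)) for i in herd}
    state = SchemeState(
        config=config,
        gmap=hist.gmap,
        effects=effects,
        pedigree=ped,
        haplo=haplo,
        herd=herd,
        herd_of=herd_of,
        active_sires=[(int(i), birth) for i in range(sch.n_cows, n_f)],
        cohort_range={birth: (0, n_f)},
        hys_effects={},
        _seedseq=ss,
        _rng=rng,
    )
    state.p_base_freqs = allele_frequencies(state.marker_genotypes(np.arange(n_f)))
    return state, effects


def _hys_effect(state: SchemeState, key) -> float:
    if key not in state.hys_effects:
        state.hys_effects[key] = float(
            state._rng.standard_normal() * state.config.trait.hys_sd
        )
    return state.hys_effects[key]


def _evaluate(state: SchemeState, genomic: bool) -> np.ndarray:
    """BLUP (or ssGBLUP) breeding values for every animal, records to date.

    Uses the true simulation variances, mirroring routine evaluation with
    known parameters.
    """
    ped = state.pedigree
    trait = state.config.trait
    vc = state.eval_vc or (trait.base_genetic_variance, trait.residual_variance)
    if len(state.rec_animal) == 0:
        return np.zeros(ped.n)
    y = np.asarray(state.rec_value, float)
    labels = list(zip(state.rec_herd, state.rec_year, state.rec_season))
    X, _ = hys_design(labels)
    ainv = a_inverse(ped)
    kinv = ainv
    geno = state.genotyped_idx()
    if genomic and geno.size > 0:
        g2 = state.marker_genotypes(geno)
        Z = center_markers(g2, state.p_base_freqs, "P-base")
        G = g_matrix(Z)
        A22 = a_submatrix(ainv, geno)
        Gb = blend_g(G, A22, state.config.g_blend_weight)
        kinv = h_inverse(ainv, Gb, np.linalg.inv(A22), geno)
    spec = MixedModelSpec(
        y=y,
        X=X,
        rec_animal=np.asarray(state.rec_animal, np.int64),
        n_animals=ped.n,
        k_inverse=kinv,
    )
    _, ebv = solve_blup(spec, vc)
    return ebv


def _parent_average(state: SchemeState, idx: np.ndarray, ebv: np.ndarray) -> np.ndarray:
    s, d = state.pedigree.sire[idx], state.pedigree.dam[idx]
    pa_s = np.where(s >= 0, ebv[np.clip(s, 0, None)], 0.0)
    pa_d = np.where(d >= 0, ebv[np.clip(d, 0, None)], 0.0)
    return 0.5 * (pa_s + pa_d)


def _top_k(idx: np.ndarray, crit: np.ndarray, k: int, rng, random_selection=False) -> np.ndarray:
    """Truncation selection with random tie-breaking (or pure random choice)."""
    if k >= idx.size:
        return idx
    if random_selection:
        return rng.choice(idx, k, replace=False)
    jitter = rng.random(idx.size) * 1e-12
    order = np.argsort(-(crit + jitter), kind="stable")
    return idx[order[:k]]


def _mate(state: SchemeState, year: int) -> None:
    """Every herd cow produces one calf from a random active sire."""
    sch = state.config.scheme
    rng = state._rng
    dams = state.herd
    pool = np.array([s for s, y0 in state.active_sires if year - y0 < sch.sire_service_years])
    if pool.size == 0:
        raise RuntimeError("no active sires available")
    sires = pool[rng.integers(0, pool.size, dams.size)]
    seed_s = state._spawn_seed()
    seed_d = state._spawn_seed()
    gam_s = make_gametes(state.haplo, sires, state.gmap, seed_s)
    gam_d = make_gametes(state.haplo, dams, state.gmap, seed_d)
    calves = np.stack([gam_s, gam_d], axis=1)
    sex = (rng.random(dams.size) < 0.5).astype(np.uint8)  # 1 = bull
    tbv = state.effects.breeding_values(calves)
    start = state.pedigree.n
    state.pedigree.append(sires, dams, sex, year, tbv)
    state.haplo = np.concatenate([state.haplo, calves], axis=0)
    state.cohort_range[year] = (start, state.pedigree.n)


def _replace_and_record(state: SchemeState, year: int) -> None:
    """Random culling; heifers born year-2 enter first lactation and record."""
    sch, trait = state.config.scheme, state.config.trait
    rng = state._rng
    pool = state.cohort(year - 2)
    heifers = pool[state.pedigree.sex[pool] == 0]
    n_new = min(sch.n_replacements_per_year, heifers.size)
    if n_new == 0:
        return
    new_cows = rng.choice(heifers, n_new, replace=False)
    cull = rng.choice(state.herd.size, n_new, replace=False)
    keep = np.delete(state.herd, cull)
    state.herd = np.concatenate([keep, new_cows])
    for cow in new_cows:
        herd_id = int(rng.integers(0, sch.n_herds))
        state.herd_of[int(cow)] = herd_id
        season = int(rng.integers(0, sch.n_seasons))
        mu = _hys_effect(state, (herd_id, year, season))
        e = float(rng.standard_normal() * np.sqrt(trait.residual_variance))
        state.rec_animal.append(int(cow))
        state.rec_value.append(mu + state.pedigree.tbv[cow] + e)
        state.rec_herd.append(herd_id)
        state.rec_year.append(year)
        state.rec_season.append(season)


def _mark_proven(state: SchemeState) -> None:
    """Progeny-tested young bulls (non-founder sires with phenotyped
    daughters) are proven and genotyped at the end of the conventional
    phase; base-population sires are not part of the genotyped cohorts."""
    rec = np.asarray(state.rec_animal, np.int64)
    sires = np.unique(state.pedigree.sire[rec][state.pedigree.sire[rec] >= 0])
    proven = sires[~state.pedigree.founder_mask[sires]]
    state.pedigree.is_proven[proven] = True
    state.pedigree.is_genotyped[proven] = True


def run_conventional_phase(state: SchemeState) -> SchemeState:
    """Setup years plus the progeny-test phase (years 1..Y1)."""
    sch = state.config.scheme
    rng = state._rng
    for year in range(1 - sch.setup_years, 1):  # random-mating setup years
        _mate(state, year)
    for year in range(1, sch.years_conventional + 1):
        ebv = (
            np.zeros(state.pedigree.n)
            if sch.random_selection
            else _evaluate(state, genomic=False)
        )
        candidates = state.cohort(year - 1)
        bulls = candidates[state.pedigree.sex[candidates] == 1]
        if bulls.size and sch.n_young_bulls_selected:
            pa = _parent_average(state, bulls, ebv)
            chosen = _top_k(bulls, pa, sch.n_young_bulls_selected, rng, sch.random_selection)
            state.active_sires.extend((int(b), year) for b in chosen)
        _replace_and_record(state, year)
        _mate(state, year)
        state.year = year
    _mark_proven(state)
    return state


def run_gs_phase(state: SchemeState, vc_for_evaluation=None) -> SchemeState:
    """Genomic-selection phase: PA pre-selection for genotyping, GEBV sires."""
    sch = state.config.scheme
    rng = state._rng
    y1 = sch.years_conventional
    state.eval_vc = vc_for_evaluation
    for year in range(y1 + 1, y1 + sch.years_gs + 1):
        candidates = state.cohort(year - 1)
        bulls = candidates[state.pedigree.sex[candidates] == 1]
        heifers = candidates[state.pedigree.sex[candidates] == 0]
        if sch.n_bulls_genotyped_per_year == 0:
            # degenerate configuration: fall back to conventional PA selection
            ebv = (
                np.zeros(state.pedigree.n)
                if sch.random_selection
                else _evaluate(state, genomic=False)
            )
            if bulls.size and sch.n_young_bulls_selected:
                pa = _parent_average(state, bulls, ebv)
                chosen = _top_k(bulls, pa, sch.n_young_bulls_selected, rng, sch.random_selection)
                state.active_sires.extend((int(b), year) for b in chosen)
        else:
            pa_ebv = (
                np.zeros(state.pedigree.n)
                if sch.random_selection
                else _evaluate(state, genomic=True)
            )
            geno_bulls = _top_k(
                bulls,
                _parent_average(state, bulls, pa_ebv),
                sch.n_bulls_genotyped_per_year,
                rng,
                sch.random_selection,
            )
            geno_heifers = _top_k(
                heifers,
                _parent_average(state, heifers, pa_ebv),
                sch.n_heifers_genotyped_per_year,
                rng,
                sch.random_selection,
            )
            state.pedigree.is_genotyped[geno_bulls] = True
            state.pedigree.is_genotyped[geno_heifers] = True
            gebv = (
                np.zeros(state.pedigree.n)
                if sch.random_selection
                else _evaluate(state, genomic=True)
            )
            chosen = _top_k(
                geno_bulls, gebv[geno_bulls], sch.n_sires_selected_gs, rng, sch.random_selection
            )
            state.active_sires.extend((int(b), year) for b in chosen)
        _replace_and_record(state, year)
        _mate(state, year)
        state.year = year
    return state


@dataclass
class SimOutput:
    """One complete replicate: pedigree, records, haplotypes, truths."""

    state: SchemeState

    @property
    def pedigree(self) -> PedigreeBook:
        return self.state.pedigree

    @property
    def phenotypes(self) -> pd.DataFrame:
        return self.state.phenotypes

    @property
    def config(self) -> SimulationConfig:
        return self.state.config

    def founders(self) -> np.ndarray:
        return np.flatnonzero(self.pedigree.founder_mask)

    def p_base_variance(self) -> float:
        return true_vc(self.pedigree.tbv, self.founders())

    def g_base_variance(self) -> float:
        return true_vc(self.pedigree.tbv, self.state.g_base_cohort())

    def final_year_variance(self) -> float:
        last = self.config.scheme.total_years
        return true_vc(self.pedigree.tbv, self.state.cohort(last))

    def p_base_freqs(self) -> np.ndarray:
        return self.state.p_base_freqs

    def g_base_freqs(self) -> np.ndarray:
        return allele_frequencies(self.state.marker_genotypes(self.state.g_base_cohort()))


def simulate(config: SimulationConfig, seed: int) -> SimOutput:
    """Run one full replicate: historical burn-in through the GS phase."""
    ss = np.random.SeedSequence(seed)
    s_hist, s_panel, s_scheme = (int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(3))
    hist = run_historical(config.genome, config.historical, s_hist)
    panel = select_loci(hist, config.panel.n_markers, config.panel.n_qtl, s_panel)
    state, _ = make_founders(panel, config.trait.base_genetic_variance, config, s_scheme)
    run_conventional_phase(state)
    run_gs_phase(state)
    return SimOutput(state=state)
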