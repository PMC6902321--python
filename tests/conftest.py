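"""Shared fixtures.

The expensive objects (replicated mini-scale simulations and their model
fits) are built once per session and shared across the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import gsvcbias as g
from gsvcbias.experiment import default_scenarios, fit_pam, fit_ssbr, fit_ssgblup

MASTER_SEED = 20240917


def micro_config() -> g.SimulationConfig:
    """A very small but structurally complete program for fast unit tests."""
    return g.SimulationConfig(
        genome=g.GenomeConfig(n_chromosomes=2, markers_per_chrom=400, qtl_per_chrom=80),
        historical=g.HistoricalConfig(n_generations=80, pop_size=60),
        panel=g.PanelConfig(n_markers=120, n_qtl=40),
        scheme=g.SchemeConfig(
            years_conventional=5,
            years_gs=3,
            n_cows=80,
            n_replacements_per_year=32,
            n_founder_bulls=10,
            n_young_bulls_selected=3,
            n_bulls_genotyped_per_year=8,
            n_heifers_genotyped_per_year=20,
            n_sires_selected_gs=3,
            n_herds=2,
        ),
    )


@pytest.fixture(scope="session")
def micro_cfg():
    return micro_config()


@pytest.fixture(scope="session")
def micro_sim(micro_cfg):
    return g.simulate(micro_cfg, 1234)


class ReplicateSuite:
    """Five mini-scale replicates with lazily cached model fits."""

    def __init__(self, n_replicates: int = 5, master_seed: int = MASTER_SEED):
        self.config = g.mini_scale()
        ss = np.random.SeedSequence(master_seed)
        self.seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n_replicates)]
        self._sims = None
        self._fits = {}

    @property
    def sims(self):
        if self._sims is None:
            self._sims = [g.simulate(self.config, s) for s in self.seeds]
        return self._sims

    @property
    def scenarios(self):
        return default_scenarios(self.config)

    def pam(self, scenario: str):
        key = ("P-AM", scenario)
        if key not in self._fits:
            spec = self.scenarios[scenario]
            self._fits[key] = [fit_pam(sim, spec) for sim in self.sims]
        return self._fits[key]

    def ssgblup(self, scenario: str):
        key = ("ssGBLUP", scenario)
        if key not in self._fits:
            spec = self.scenarios[scenario]
            self._fits[key] = [fit_ssgblup(sim, spec) for sim in self.sims]
        return self._fits[key]

    def ssbr(self, scenario: str):
        key = ("ssBR", scenario)
        if key not in self._fits:
            spec = self.scenarios[scenario]
            self._fits[key] = [
                fit_ssbr(sim, spec, seed=self.seeds[i] + 1)
                for i, sim in enumerate(self.sims)
            ]
        return self._fits[key]

    # truth summaries -----------------------------------------------------
    def p_base(self):
        return np.array([s.p_base_variance() for s in self.sims])

    def g_base(self):
        return np.array([s.g_base_variance() for s in self.sims])

    def final_cohort(self):
        return np.array([s.final_year_variance() for s in self.sims])


@pytest.fixture(scope="session")
def suite():
    return ReplicateSuite()


def mean_se(values) -> tuple[float, float]:
    v = np.asarray(values, float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
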