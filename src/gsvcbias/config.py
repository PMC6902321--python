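"""Configuration objects and scale presets.

A single :class:`SimulationConfig` describes one complete study condition:
the neutral historical phase that builds linkage disequilibrium, the marker/
QTL panel sampled from it, the trait (base genetic and residual variance),
and the 35-year breeding scheme (conventional progeny-test phase followed by
a genomic-selection phase).

Three presets are provided:

* ``full_scale`` -- the full Jersey-like program (10,000 cows, 30
  chromosomes, 40k markers).  Accepted by every routine but far beyond what
  the bundled tests run.
* ``desk_scale``  -- a 1/10 program retaining the selected proportions.
* ``mini_scale``  -- the default study condition for the bundled experiment:
  a 250-cow herd on a 3-chromosome genome, sized so that a full replicate
  (simulation + all nine model x scenario fits) runs in minutes on one CPU
  while preserving the selection intensities that drive the variance-bias
  phenomenon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class GenomeConfig:
    """Genome layout of the locus *pools* simulated in the historical phase."""

    n_chromosomes: int = 30
    chrom_length_cm: float = 100.0
    markers_per_chrom: int = 10_000
    qtl_per_chrom: int = 100


@dataclass(frozen=True)
class HistoricalConfig:
    """Neutral burn-in that creates mutation-drift equilibrium LD."""

    n_generations: int = 3000
    pop_size: int = 400
    mutation_rate: float = 2.5e-5  # recurrent symmetric flip / locus / meiosis
    initial_frequency: float = 0.5


@dataclass(frozen=True)
class PanelConfig:
    """Loci retained for the breeding phases (sampled from segregating pools)."""

    n_markers: int = 40_000
    n_qtl: int = 2_000


@dataclass(frozen=True)
class TraitConfig:
    base_genetic_variance: float = 3.59  # variance of founder TBVs (exact, by scaling)
    residual_variance: float = 5.05
    hys_sd: float = 1.0  # SD of herd-year-season effects

    @property
    def heritability(self) -> float:
        g, e = self.base_genetic_variance, self.residual_variance
        return g / (g + e)


@dataclass(frozen=True)
class SchemeConfig:
    """Breeding-program structure.

    ``n_replacements_per_year`` first-lactation cows enter the herd (and are
    phenotyped) each year; the herd is kept at ``n_cows`` by random culling.
    Young bulls are truncation-selected on parent average; in the GS phase
    bull and heifer calves are pre-selected on PA for genotyping and sires
    are then chosen on ssGBLUP GEBV.
    """

    years_conventional: int = 20
    years_gs: int = 15
    n_cows: int = 10_000
    n_replacements_per_year: int = 4_000
    n_founder_bulls: int = 250
    n_young_bulls_selected: int = 50
    n_bulls_genotyped_per_year: int = 500
    n_heifers_genotyped_per_year: int = 2_000
    n_sires_selected_gs: int = 50
    sire_service_years: int = 4
    n_herds: int = 100
    n_seasons: int = 4
    setup_years: int = 2  # pre-scheme random-mating years providing early heifers
    random_selection: bool = False  # replace every truncation selection by random choice

    def __post_init__(self) -> None:
        if self.n_replacements_per_year > self.n_cows:
            raise ValueError("replacements per year cannot exceed herd size")
        if 0 < self.n_bulls_genotyped_per_year < self.n_sires_selected_gs:
            raise ValueError("GS sires selected must be <= bulls genotyped per year")

    @property
    def total_years(self) -> int:
        return self.years_conventional + self.years_gs


@dataclass(frozen=True)
class SsbrChainConfig:
    """Gibbs chain lengths.  Full scale: 50,000 / 20,000."""

    n_iter: int = 10_000
    burn_in: int = 4_000
    mce_batch: int = 100


@dataclass(frozen=True)
class SimulationConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    historical: HistoricalConfig = field(default_factory=HistoricalConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    trait: TraitConfig = field(default_factory=TraitConfig)
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    g_blend_weight: float = 0.05  # Gb = (1-w) G + w A22

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def full_scale() -> SimulationConfig:
    """The full-size program as published (not desk-runnable)."""
    return SimulationConfig()


def desk_scale() -> SimulationConfig:
    """~1/10 program: 5 chromosomes, 2000-marker panel, 1000-cow herd."""
    return SimulationConfig(
        genome=GenomeConfig(n_chromosomes=5, markers_per_chrom=3_000, qtl_per_chrom=150),
        historical=HistoricalConfig(n_generations=200, pop_size=100),
        panel=PanelConfig(n_markers=2_000, n_qtl=200),
        scheme=SchemeConfig(
            years_conventional=10,
            years_gs=8,
            n_cows=1_000,
            n_replacements_per_year=400,
            n_founder_bulls=50,
            n_young_bulls_selected=10,
            n_bulls_genotyped_per_year=100,
            n_heifers_genotyped_per_year=400,
            n_sires_selected_gs=10,
            n_herds=10,
        ),
    )


def mini_scale() -> SimulationConfig:
    """Default study condition for the bundled experiment and tests.

    250-cow herd, 100 first lactations/yr, 4 young bulls/yr (PA truncation),
    GS phase genotypes 20 bull + 60 heifer calves/yr and keeps the top 4
    bulls by GEBV.  Records-per-HYS-class (~8) and the selected proportions
    on the sire path track the published program.
    """
    return SimulationConfig(
        genome=GenomeConfig(n_chromosomes=3, markers_per_chrom=2_000, qtl_per_chrom=200),
        historical=HistoricalConfig(n_generations=200, pop_size=100),
        panel=PanelConfig(n_markers=600, n_qtl=150),
        scheme=SchemeConfig(
            years_conventional=10,
            years_gs=8,
            n_cows=250,
            n_replacements_per_year=100,
            n_founder_bulls=25,
            n_young_bulls_selected=4,
            n_bulls_genotyped_per_year=20,
            n_heifers_genotyped_per_year=60,
            n_sires_selected_gs=4,
            n_herds=3,
        ),
    )
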