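"""Scenario slicing, replicate orchestration and Table-style reporting.

Three phenotype windows define the scenarios:

* ``pheno1``  -- conventional-phase records only (years 1..Y1), analysed as
  the end-of-phase snapshot: pedigree truncated there and only the proven
  bulls genotyped; marker matrices centred on P-base (founder) frequencies;
* ``pheno12`` -- all records (years 1..Y1+Y2), full pedigree, all
  genotypes, P-base frequencies;
* ``pheno2``  -- GS-phase records only, full pedigree, all genotypes,
  G-base frequencies (the cohort born in the last three conventional
  years).

Each replicate simulates once, computes the P-base/G-base/final-cohort
truths from TBVs, and fits any of the three models (pedigree animal model,
ssGBLUP, ssBR) on any scenario.  Reporting follows the published layout:
replicate means (SD) with paired-t significance stars against the simulated
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .breeding import SimOutput, simulate
from .config import SimulationConfig, SsbrChainConfig
from .relationships import (
    a_inverse,
    a_submatrix,
    blend_g,
    center_markers,
    g_matrix,
    h_submatrix,
)
from .reml import MixedModelSpec, VcEstimate, fit_reml, hys_design
from .ssbr import SsbrPriors, build_ssbr_model, marker_genetic_variance, monte_carlo_error, run_gibbs

__all__ = [
    "ScenarioSpec",
    "default_scenarios",
    "slice_scenario",
    "fit_pam",
    "fit_ssgblup",
    "fit_ssbr",
    "SsbrEstimate",
    "ReplicateResult",
    "run_replicate",
    "run_experiment",
    "significance_vs_truth",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which records, genotypes and allele-frequency base define an analysis."""

    name: str
    year_lo: int
    year_hi: int
    freq_base: str  # "P-base" | "G-base"
    genotype_set: str  # "proven" | "all"
    snapshot: bool  # truncate pedigree at the end of the phenotype window


def default_scenarios(config: SimulationConfig) -> dict[str, ScenarioSpec]:
    y1 = config.scheme.years_conventional
    y2 = config.scheme.total_years
    return {
        "pheno1": ScenarioSpec("pheno1", 1, y1, "P-base", "proven", True),
        "pheno12": ScenarioSpec("pheno12", 1, y2, "P-base", "all", False),
        "pheno2": ScenarioSpec("pheno2", y1 + 1, y2, "G-base", "all", False),
    }


@dataclass
class SlicedData:
    """Model-ready view of one scenario."""

    records: pd.DataFrame
    n_animals: int
    genotyped: np.ndarray
    freqs: np.ndarray
    spec: ScenarioSpec

    def design(self):
        X, _ = hys_design(
            list(zip(self.records["herd"], self.records["year"], self.records["season"]))
        )
        return X


def slice_scenario(sim: SimOutput, spec: ScenarioSpec) -> SlicedData:
    if spec.year_hi < spec.year_lo:
        raise ValueError(f"empty phenotype window ({spec.year_lo}, {spec.year_hi})")
    ph = sim.phenotypes
    rec = ph[(ph["year"] >= spec.year_lo) & (ph["year"] <= spec.year_hi)].reset_index(drop=True)
    if rec.empty:
        raise ValueError("no phenotype records in the requested window")
    ped = sim.pedigree
    if spec.snapshot:
        n_animals = int(np.searchsorted(ped.birth_year, spec.year_hi, side="right"))
    else:
        n_animals = ped.n
    if spec.genotype_set == "proven":
        geno = np.flatnonzero(ped.is_proven[:n_animals])
    else:
        geno = np.flatnonzero(ped.is_genotyped[:n_animals])
    freqs = sim.p_base_freqs() if spec.freq_base == "P-base" else sim.g_base_freqs()
    return SlicedData(records=rec, n_animals=n_animals, genotyped=geno, freqs=freqs, spec=spec)


def _truncated_pedigree(sim: SimOutput, n_animals: int):
    class _View:
        sire = sim.pedigree.sire[:n_animals]
        dam = sim.pedigree.dam[:n_animals]

    return _View()


def fit_pam(sim: SimOutput, spec: ScenarioSpec, **reml_kw) -> VcEstimate:
    """Pedigree animal model by AI-REML."""
    data = slice_scenario(sim, spec)
    ainv = a_inverse(_truncated_pedigree(sim, data.n_animals))
    mspec = MixedModelSpec(
        y=data.records["value"].to_numpy(float),
        X=data.design(),
        rec_animal=data.records["animal"].to_numpy(np.int64),
        n_animals=data.n_animals,
        k_inverse=ainv,
    )
    est = fit_reml(mspec, **reml_kw)
    est.model, est.scenario = "P-AM", spec.name
    return est


def fit_ssgblup(sim: SimOutput, spec: ScenarioSpec, **reml_kw) -> VcEstimate:
    """Single-step GBLUP by AI-REML (H relationship among recorded animals)."""
    data = slice_scenario(sim, spec)
    ainv = a_inverse(_truncated_pedigree(sim, data.n_animals))
    geno = data.genotyped
    rows = data.records["animal"].to_numpy(np.int64)
    g2 = sim.state.marker_genotypes(geno)
    G = g_matrix(center_markers(g2, data.freqs, spec.freq_base))
    A22 = a_submatrix(ainv, geno)
    Gb = blend_g(G, A22, sim.config.g_blend_weight)
    uniq, inv = np.unique(rows, return_inverse=True)
    H_rr = h_submatrix(ainv, geno, Gb, uniq)[np.ix_(inv, inv)]
    mspec = MixedModelSpec(
        y=data.records["value"].to_numpy(float),
        X=data.design(),
        rec_animal=rows,
        n_animals=data.n_animals,
        k_inverse=ainv,
        k_records=H_rr,
    )
    est = fit_reml(mspec, **reml_kw)
    est.model, est.scenario = "ssGBLUP", spec.name
    return est


@dataclass
class SsbrEstimate:
    """Posterior summaries from one single-step Bayesian regression fit."""

    total_genetic: float  # posterior mean of sigma_eps^2
    total_genetic_sd: float
    marker_genetic: float  # posterior mean of sigma_alpha^2 * sum 2pq
    marker_genetic_sd: float
    residual: float
    residual_sd: float
    heritability: float
    mce_total: float
    mce_marker: float
    mce_residual: float
    model: str = "ssBR"
    scenario: str = ""


def fit_ssbr(
    sim: SimOutput,
    spec: ScenarioSpec,
    seed: int,
    priors: SsbrPriors | None = None,
    chain: SsbrChainConfig | None = None,
) -> SsbrEstimate:
    data = slice_scenario(sim, spec)
    priors = priors or SsbrPriors()
    chain_cfg = chain or SsbrChainConfig()
    ainv = a_inverse(_truncated_pedigree(sim, data.n_animals))
    g2 = sim.state.marker_genotypes(data.genotyped)
    model = build_ssbr_model(
        sim.pedigree, data.records, data.genotyped, g2, data.freqs, ainv, spec.freq_base
    )
    post = run_gibbs(model, priors, chain_cfg, seed)
    mk_mean, mk_sd = marker_genetic_variance(post, data.freqs)
    b = chain_cfg.mce_batch
    return SsbrEstimate(
        total_genetic=post.posterior_mean("eps"),
        total_genetic_sd=post.posterior_sd("eps"),
        marker_genetic=mk_mean,
        marker_genetic_sd=mk_sd,
        residual=post.posterior_mean("e"),
        residual_sd=post.posterior_sd("e"),
        heritability=post.heritability(),
        mce_total=monte_carlo_error(post.kept("eps"), b),
        mce_marker=monte_carlo_error(post.kept("alpha") * model.sum2pq, b),
        mce_residual=monte_carlo_error(post.kept("e"), b),
        scenario=spec.name,
    )


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    p_base: float
    g_base: float
    final_cohort: float
    estimates: dict = field(default_factory=dict)  # (model, scenario) -> dict
    errors: dict = field(default_factory=dict)


def run_replicate(
    config: SimulationConfig,
    seed: int,
    replicate: int = 0,
    models: tuple = ("P-AM", "ssGBLUP", "ssBR"),
    scenarios: tuple = ("pheno1", "pheno12", "pheno2"),
    priors: SsbrPriors | None = None,
    chain: SsbrChainConfig | None = None,
) -> ReplicateResult:
    """Simulate one replicate and fit the requested model x scenario grid."""
    sim = simulate(config, seed)
    res = ReplicateResult(
        replicate=replicate,
        seed=seed,
        p_base=sim.p_base_variance(),
        g_base=sim.g_base_variance(),
        final_cohort=sim.final_year_variance(),
    )
    scen = default_scenarios(config)
    for sname in scenarios:
        spec = scen[sname]
        for model in models:
            key = (model, sname)
            try:
                if model == "P-AM":
                    est = fit_pam(sim, spec)
                    res.estimates[key] = {
                        "genetic": est.genetic_variance,
                        "residual": est.residual_variance,
                        "h2": est.heritability,
                    }
                elif model == "ssGBLUP":
                    est = fit_ssgblup(sim, spec)
                    res.estimates[key] = {
                        "genetic": est.genetic_variance,
                        "residual": est.residual_variance,
                        "h2": est.heritability,
                    }
                elif model == "ssBR":
                    est = fit_ssbr(sim, spec, seed=seed + 17 * replicate + 1, priors=priors, chain=chain)
                    res.estimates[key] = {
                        "genetic": est.total_genetic,
                        "residual": est.residual,
                        "marker": est.marker_genetic,
                        "h2": est.heritability,
                        "mce_total": est.mce_total,
                        "mce_marker": est.mce_marker,
                    }
                else:  # pragma: no cover
                    raise ValueError(f"unknown model {model}")
            except Exception as exc:  # record and continue with the grid
                res.errors[key] = repr(exc)
    return res


def significance_vs_truth(estimates, truths) -> tuple[float, str]:
    """Paired two-sided t-test of per-replicate (estimate - truth) against 0.

    Stars follow the published convention: * P<0.01, ** P<0.005, *** P<0.001.
    """
    d = np.asarray(estimates, float) - np.asarray(truths, float)
    if d.size < 2:
        raise ValueError("need at least two replicates")
    if np.allclose(d, 0.0):
        return 1.0, ""
    if np.allclose(d, d[0]):
        return 0.0, "***"
    p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return p, stars_for_p(p)


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.01:
        return "*"
    return ""


@dataclass
class ExperimentResult:
    replicates: list
    summary: pd.DataFrame

    def to_text(self) -> str:
        def cell(r, quant):
            mean = r.get(f"{quant}_mean", np.nan)
            if not np.isfinite(mean):
                return "-"
            sd = r.get(f"{quant}_sd", np.nan)
            sd_txt = f" ({sd:.2f})" if np.isfinite(sd) else ""
            return f"{mean:.2f}{sd_txt}{r.get(f'{quant}_stars', '')}"

        lines = ["model      scenario   genetic          residual         marker           h2"]
        for _, r in self.summary.iterrows():
            lines.append(
                f"{r['model']:<10} {r['scenario']:<10} "
                f"{cell(r, 'genetic'):<16} {cell(r, 'residual'):<16} "
                f"{cell(r, 'marker'):<16} {cell(r, 'h2')}"
            )
        return "\n".join(lines)


def run_experiment(
    config: SimulationConfig,
    master_seed: int,
    n_replicates: int = 5,
    models: tuple = ("P-AM", "ssGBLUP", "ssBR"),
    scenarios: tuple = ("pheno1", "pheno12", "pheno2"),
    chain: SsbrChainConfig | None = None,
) -> ExperimentResult:
    """Full factorial over replicates; returns per-cell means, SDs and stars."""
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n_replicates)]
    reps = [
        run_replicate(config, seeds[r], r, models=models, scenarios=scenarios, chain=chain)
        for r in range(n_replicates)
    ]
    rows = []
    p_truth = [r.p_base for r in reps]
    g_truth = [r.g_base for r in reps]
    for model in models:
        for sname in scenarios:
            cells = [r.estimates.get((model, sname)) for r in reps]
            cells = [c for c in cells if c is not None]
            if not cells:
                continue
            row = {"model": model, "scenario": sname, "n": len(cells)}
            truth = g_truth if sname == "pheno2" else p_truth
            for quant in ("genetic", "residual", "marker", "h2"):
                vals = [c[quant] for c in cells if quant in c]
                if not vals:
                    row[f"{quant}_mean"] = np.nan
                    row[f"{quant}_sd"] = np.nan
                    row[f"{quant}_stars"] = ""
                    continue
                row[f"{quant}_mean"] = float(np.mean(vals))
                row[f"{quant}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
                if quant in ("genetic", "marker") and len(vals) == len(truth) and len(vals) > 1:
                    _, stars = significance_vs_truth(vals, truth[: len(vals)])
                    row[f"{quant}_stars"] = stars
                elif quant == "residual" and len(vals) > 1:
                    se_truth = [config.trait.residual_variance] * len(vals)
                    _, stars = significance_vs_truth(vals, se_truth)
                    row[f"{quant}_stars"] = stars
                else:
                    row[f"{quant}_stars"] = ""
            rows.append(row)
    truth_rows = [
        {"model": "truth", "scenario": "P-base", "genetic_mean": float(np.mean(p_truth)),
         "genetic_sd": float(np.std(p_truth, ddof=1)) if len(p_truth) > 1 else np.nan},
        {"model": "truth", "scenario": "G-base", "genetic_mean": float(np.mean(g_truth)),
         "genetic_sd": float(np.std(g_truth, ddof=1)) if len(g_truth) > 1 else np.nan},
    ]
    summary = pd.DataFrame(rows + truth_rows).fillna({"genetic_stars": "", "residual_stars": "",
                                                      "marker_stars": "", "h2_stars": ""})
    return ExperimentResult(replicates=reps, summary=summary)
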