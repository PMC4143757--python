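"""Replicate-level orchestration: empirical type-I error and power tables.

Emulating the evaluation design of family genetic-analysis workshops, a
study consists of a fixed pedigree (so the relationship matrix and its
eigendecomposition are computed once) and many replicates in which
genotypes are re-dropped and traits re-simulated.  Per replicate the
covariates-only polygenic null model is fitted once per trait and every
variant set is tested with famBT and famSKAT under both selection schemes:

* GB — gene-based: rare nonsynonymous/splice variants per gene;
* SW — sliding windows: all rare variants per 4000-bp window, 2000-bp step.

Type-I error pools set-level p-values of a pure-null trait across sets and
replicates and reports rejection proportions with exact binomial CIs.
Power uses per-replicate decisions: the gene-based p-value against the
gene-level genome-wide threshold (2.5e-6), and for windows the minimum p
over the windows overlapping the gene multiplied by 60 (a conservative
fixed multiple-testing adjustment; the windows are correlated) against the
window-level threshold (3.3e-8).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import kinship_matrix
from .lmm import fit_null
from .phenotype import build_analysis_table, exclude_medicated, select_baseline
from .settests import run_set_tests
from .simulate import (
    SimulationConfig,
    gene_drop,
    map4_like_panel,
    null_panel,
    simulate_pedigree,
    simulate_traits,
)
from .variants import gene_based_sets, sliding_windows, window_sets

__all__ = [
    "run_type1",
    "run_power",
    "adjust_min_p",
    "GB_THRESHOLD",
    "SW_THRESHOLD",
    "CANDIDATE_THRESHOLD",
]

log = logging.getLogger("famrv")

#: genome-wide gene-based threshold (~20,000 genes)
GB_THRESHOLD = 2.5e-6
#: genome-wide sliding-window threshold (~1.5 million windows)
SW_THRESHOLD = 3.3e-8
#: candidate-gene threshold, 0.05 Bonferroni-corrected for 8 genes
CANDIDATE_THRESHOLD = 0.05 / 8


def adjust_min_p(p_values, multiplier: float = 60.0) -> float:
    """Bonferroni-style region summary: ``min(1, multiplier * min(p))``.

    Conservative when the tests (overlapping windows) are correlated.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("adjust_min_p needs at least one p-value")
    return float(min(1.0, multiplier * p.min()))


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    a = 1.0 - level
    lo = stats.beta.ppf(a / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def _trait_fit(pheno: pd.DataFrame, trait: str, phi, phi_eig, dm):
    """Baseline pipeline -> analysis table -> null fit.

    Phi and its eigendecomposition are precomputed in pedigree order, so the
    analysis table must come out in exactly that order; anything else is a
    hard error rather than a silent misalignment.
    """
    base = exclude_medicated(select_baseline(pheno))
    at = build_analysis_table(base, trait)
    if at.ids != list(dm.sample_ids):
        raise RuntimeError("analysis table order diverged from dosage/kinship order")
    fit = fit_null(at.y, at.x, phi, phi_eig=phi_eig)
    return at, dm, fit


def _study_setup(config: SimulationConfig, panel, genes):
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ped = simulate_pedigree(config, rng)
    rel = kinship_matrix(ped)
    phi = rel.phi
    d, u = np.linalg.eigh(phi)
    return rng, ped, phi, (np.maximum(d, 0.0), u)


def run_type1(
    config: SimulationConfig,
    n_replicates: int = 200,
    panel: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    alphas: tuple[float, ...] = (0.05, 0.001),
    trait: str = "q1",
    collect_pvalues: bool = False,
):
    """Empirical type-I error of famBT/famSKAT under GB and SW selection.

    Simulates ``n_replicates`` data sets with a pure-null polygenic trait,
    pools the set-level p-values across sets and replicates, and reports
    the rejection proportion at each ``alpha`` with an exact binomial 95%
    CI.  With ``collect_pvalues`` the pooled p-value frame is returned too.
    """
    if panel is None:
        panel, genes = null_panel()
    if genes is None:
        raise ValueError("a gene table must accompany a custom panel")
    rng, ped, phi, phi_eig = _study_setup(config, panel, genes)
    extent_end = int(panel["pos"].max()) + 1
    windows = sliding_windows(str(panel["chrom"].iloc[0]), 1, extent_end)
    frames = []
    for rep in range(n_replicates):
        dm = gene_drop(ped, panel, rng)
        pheno = simulate_traits(ped, dm, panel, config, rng, phi=phi)
        _, dm_a, fit = _trait_fit(pheno, trait, phi, phi_eig, dm)
        gb = run_set_tests(fit, dm_a, gene_based_sets(dm_a, genes), trait=trait)
        sw = run_set_tests(fit, dm_a, window_sets(dm_a, windows), trait=trait)
        gb["selection"] = "GB"
        sw["selection"] = "SW"
        both = pd.concat([gb, sw], ignore_index=True)
        both["replicate"] = rep
        frames.append(both)
        if (rep + 1) % 50 == 0:
            log.info("run_type1: %d/%d replicates done", rep + 1, n_replicates)
    pooled = pd.concat(frames, ignore_index=True)
    rows = []
    for (method, selection), grp in pooled.groupby(["method", "selection"]):
        p = grp["p"].to_numpy()
        for alpha in alphas:
            k = int((p < alpha).sum())
            lo, hi = _binom_ci(k, p.size)
            rows.append(
                {"method": method, "selection": selection, "alpha": alpha,
                 "n_tests": p.size, "rejections": k, "proportion": k / p.size,
                 "ci_low": lo, "ci_high": hi}
            )
    table = pd.DataFrame(rows).sort_values(
        ["selection", "method", "alpha"], ascending=[True, True, False]
    ).reset_index(drop=True)
    return (table, pooled) if collect_pvalues else table


def run_power(
    config: SimulationConfig,
    n_replicates: int = 100,
    panel: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    gb_alpha: float = GB_THRESHOLD,
    sw_alpha: float = SW_THRESHOLD,
    multiplier: float = 60.0,
    traits: tuple[str, ...] = ("dbp", "sbp"),
) -> pd.DataFrame:
    """Empirical power for the causal gene under GB and SW selection.

    Per replicate and trait: the gene-based p-value is compared with
    ``gb_alpha``; the minimum p over all windows overlapping the gene,
    multiplied by ``multiplier``, is compared with ``sw_alpha``.  Reports
    the proportion of replicates rejecting, plus the median per-replicate
    p-value (pre-adjustment for SW).
    """
    if panel is None:
        panel, genes = map4_like_panel()
    if genes is None or len(genes) != 1:
        raise ValueError("power study expects a single causal gene")
    gene = genes.iloc[0]
    rng, ped, phi, phi_eig = _study_setup(config, panel, genes)
    extent_end = int(gene.end) + 4000
    windows = [
        w for w in sliding_windows(str(gene.chrom), 1, extent_end)
        if w.end >= int(gene.start) and w.start <= int(gene.end)
    ]
    decisions: dict[tuple, list] = {}
    pvals: dict[tuple, list] = {}
    for rep in range(n_replicates):
        dm = gene_drop(ped, panel, rng)
        pheno = simulate_traits(ped, dm, panel, config, rng, phi=phi)
        for trait in traits:
            _, dm_a, fit = _trait_fit(pheno, trait, phi, phi_eig, dm)
            gb = run_set_tests(fit, dm_a, gene_based_sets(dm_a, genes), trait=trait)
            sw = run_set_tests(fit, dm_a, window_sets(dm_a, windows), trait=trait)
            for method in ("famBT", "famSKAT"):
                gp = gb.loc[gb["method"] == method, "p"]
                if len(gp) != 1:
                    raise RuntimeError(
                        f"causal gene produced {len(gp)} {method} GB tests"
                    )
                gp = float(gp.iloc[0])
                wp = sw.loc[sw["method"] == method, "p"].to_numpy()
                adj = adjust_min_p(wp, multiplier)
                decisions.setdefault((trait, method, "GB"), []).append(gp < gb_alpha)
                decisions.setdefault((trait, method, "SW"), []).append(adj < sw_alpha)
                pvals.setdefault((trait, method, "GB"), []).append(gp)
                pvals.setdefault((trait, method, "SW"), []).append(float(wp.min()))
        if (rep + 1) % 25 == 0:
            log.info("run_power: %d/%d replicates done", rep + 1, n_replicates)
    rows = []
    for (trait, method, selection), dec in decisions.items():
        alpha = gb_alpha if selection == "GB" else sw_alpha
        rows.append(
            {"trait": trait, "gene": str(gene["name"]), "method": method,
             "selection": selection, "alpha": alpha,
             "n_replicates": len(dec), "power": float(np.mean(dec)),
             "median_p": float(np.median(pvals[(trait, method, selection)]))}
        )
    return pd.DataFrame(rows).sort_values(
        ["trait", "selection", "method"]
    ).reset_index(drop=True)
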