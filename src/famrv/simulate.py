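"""Synthetic family data with the statistical structure the tests assume.

Real family blood-pressure cohorts with sequence data are access-restricted,
so this module generates stand-ins with the features that matter to the
methods: multi-generation pedigrees, rare-variant genotypes transmitted by
haplotype-level gene-dropping from founder allele frequencies (Mendelian
consistency and perfect LD between designated variant pairs are exact by
construction), and quantitative traits built as

    Y = X alpha + G beta + gamma + eps,
    gamma ~ N(0, sG2 * Phi),  eps ~ N(0, sE2 * I).

Three traits are emitted per replicate: ``q1`` (a pure-null polygenic trait
with no variant effects), ``dbp`` (mmHg-like, analyzed untransformed) and
``sbp`` (mmHg-like, analyzed rank-normalized).  Two variant panels are
provided: a null panel of many genes for type-I-error work, and a
MAP4-style effect panel with six rare coding variants (five with
same-direction negative effects plus one zero-effect perfect-LD proxy,
r = 1) and clusters of regulatory variants with balanced mixed-direction
effects — the configuration in which a burden test loses essentially all
power while the kernel test does not.

Every function is deterministic given its seed / Generator; a fixed seed
reproduces replicate files byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import Pedigree, kinship_matrix

__all__ = [
    "SimulationConfig",
    "Replicate",
    "simulate_pedigree",
    "gene_drop",
    "simulate_traits",
    "null_panel",
    "map4_like_panel",
    "simulate_replicate",
    "write_replicate",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    The defaults describe the study conditions used throughout: ~150
    three-generation families of five (two grandparents, one of their
    children, a married-in spouse, one grandchild; n = 750), polygenic
    heritability sG2/(sG2+sE2) = 0.3 on the latent trait scale, covariate
    effects for sex and age, and a smoking effect of zero (smoking is
    carried as a covariate but is not associated with the traits).
    """

    seed: int = 2014
    n_families: int = 150
    n_sibs: int = 1  # children of the grandparental couple
    n_grandchildren: int = 1  # children of the eldest child and spouse
    sigma_g2: float = 0.3
    sigma_e2: float = 0.7
    alpha_intercept: float = 0.0
    alpha_sex: float = -0.3  # female indicator
    alpha_age: float = 0.01  # per year
    alpha_smoke: float = 0.0
    sex_female_prob: float = 0.57
    age_range: tuple[float, float] = (16.0, 92.0)
    smoke_prob: float = 0.222
    # mmHg-like location/scale applied to the latent dbp/sbp traits
    dbp_loc: float = 70.5
    dbp_scale: float = 11.0
    sbp_loc: float = 118.7
    sbp_scale: float = 15.0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=True,
            )


@dataclass
class Replicate:
    """One simulated data set plus the truth that generated it."""

    index: int
    pedigree: Pedigree
    dosages: "DosageMatrix"  # noqa: F821 — forward ref, see variants module
    phenotypes: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pedigrees


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Independent three-generation families from the configured template.

    Per family: grandfather x grandmother -> ``n_sibs`` children; the eldest
    child marries a founder spouse and they have ``n_grandchildren``.  Sexes
    of non-structural members are drawn Bernoulli(``sex_female_prob``).
    PED sex coding: 1 = male, 2 = female.
    """
    if config.n_grandchildren < 1 or config.n_sibs < 1:
        raise ValueError("template must produce at least one nonfounder per branch")
    rows = []
    for f in range(config.n_families):
        fam = f"fam{f}"
        gf, gm = f"{fam}_gf", f"{fam}_gm"
        rows.append((fam, gf, "0", "0", 1))
        rows.append((fam, gm, "0", "0", 2))
        sibs = []
        for s in range(config.n_sibs):
            cid = f"{fam}_c{s}"
            sex = 2 if rng.random() < config.sex_female_prob else 1
            rows.append((fam, cid, gf, gm, sex))
            sibs.append((cid, sex))
        eldest, eldest_sex = sibs[0]
        spouse = f"{fam}_sp"
        spouse_sex = 1 if eldest_sex == 2 else 2
        rows.append((fam, spouse, "0", "0", spouse_sex))
        father, mother = (spouse, eldest) if eldest_sex == 2 else (eldest, spouse)
        for g in range(config.n_grandchildren):
            sex = 2 if rng.random() < config.sex_female_prob else 1
            rows.append((fam, f"{fam}_g{g}", father, mother, sex))
    t = pd.DataFrame(rows, columns=["family", "id", "father", "mother", "sex"])
    t["father"] = t["father"].where(t["father"] != "0", None)
    t["mother"] = t["mother"].where(t["mother"] != "0", None)
    return Pedigree(t)


# ---------------------------------------------------------------------------
# variant panels


def null_panel(
    n_genes: int = 110,
    variants_per_gene: int = 6,
    n_intergenic: int = 110,
    gene_length: int = 3000,
    gene_spacing: int = 4000,
    maf_range: tuple[float, float] = (0.005, 0.04),
    chrom: str = "1",
    seed: int = 77,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A many-gene panel with no trait effects, for type-I-error studies.

    Genes of ``gene_length`` bp tile the region every ``gene_spacing`` bp;
    each carries ``variants_per_gene`` rare nonsynonymous variants and the
    gaps hold ``n_intergenic`` unannotated rare variants, so both gene-based
    and sliding-window sets are populated.  Founder MAFs are log-uniform on
    ``maf_range``.  Returns ``(panel, genes)`` tables.
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    rows, genes = [], []
    for k in range(n_genes):
        start = 1 + k * gene_spacing
        end = start + gene_length - 1
        genes.append({"chrom": chrom, "start": start, "end": end, "name": f"gene{k}"})
        pos = np.sort(rng.choice(np.arange(start, end + 1), variants_per_gene,
                                 replace=False))
        for j, p in enumerate(pos):
            rows.append(
                {"chrom": chrom, "pos": int(p), "id": f"g{k}v{j}",
                 "founder_maf": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                 "is_nonsynonymous": True, "is_splice": False,
                 "ld_with": None, "beta_dbp": 0.0, "beta_sbp": 0.0}
            )
    extent_end = n_genes * gene_spacing
    inter = np.sort(rng.choice(np.arange(1, extent_end + 1), n_intergenic,
                               replace=False))
    for j, p in enumerate(inter):
        rows.append(
            {"chrom": chrom, "pos": int(p), "id": f"iv{j}",
             "founder_maf": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
             "is_nonsynonymous": False, "is_splice": False,
             "ld_with": None, "beta_dbp": 0.0, "beta_sbp": 0.0}
        )
    panel = pd.DataFrame(rows).sort_values("pos", kind="stable").reset_index(drop=True)
    return panel, pd.DataFrame(genes)


def map4_like_panel(
    coding_beta: float = -0.85,
    regulatory_beta: float = 1.4,
    chrom: str = "3",
    gene_start: int = 10001,
    gene_end: int = 130000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A single-gene effect panel emulating the MAP4 simulation scenario.

    Six rare coding variants: five with the same (negative) effect
    ``coding_beta`` on both traits, spaced so no 4000-bp window holds two,
    plus a sixth that is a zero-effect perfect-LD copy (r = 1) of the first.
    Three clusters of four regulatory variants carry balanced
    mixed-direction effects (+/-``regulatory_beta`` at matched MAFs), so
    within any window the expected weighted burden cancels while the kernel
    test still sees the variance signal.  Effect sizes are on the latent
    (unit-variance) trait scale; the defaults are the package's documented
    power scenario.
    """
    rows = []
    coding_pos = [12000, 30000, 52000, 74000, 96000, 118000]
    coding_maf = [0.025, 0.025, 0.03, 0.035, 0.03, 0.02]
    # index 0 is the perfect-LD proxy of index 1 and carries no effect itself
    for j, (p, m) in enumerate(zip(coding_pos, coding_maf)):
        rows.append(
            {"chrom": chrom, "pos": p, "id": f"cv{j}", "founder_maf": m,
             "is_nonsynonymous": True, "is_splice": False,
             "ld_with": "cv1" if j == 0 else None,
             "beta_dbp": 0.0 if j == 0 else coding_beta,
             "beta_sbp": 0.0 if j == 0 else coding_beta}
        )
    cluster_starts = [44000, 84000, 104000]
    cluster_maf = [0.008, 0.012, 0.008, 0.012]
    cluster_sign = [1.0, 1.0, -1.0, -1.0]
    v = 0
    for cs in cluster_starts:
        for off, m, sgn in zip((0, 400, 800, 1200), cluster_maf, cluster_sign):
            b = sgn * regulatory_beta
            rows.append(
                {"chrom": chrom, "pos": cs + off, "id": f"rv{v}", "founder_maf": m,
                 "is_nonsynonymous": False, "is_splice": False,
                 "ld_with": None, "beta_dbp": b, "beta_sbp": b}
            )
            v += 1
    panel = pd.DataFrame(rows).sort_values("pos", kind="stable").reset_index(drop=True)
    genes = pd.DataFrame(
        [{"chrom": chrom, "start": gene_start, "end": gene_end, "name": "MAP4L"}]
    )
    return panel, genes


# ---------------------------------------------------------------------------
# gene-dropping


def gene_drop(ped: Pedigree, panel: pd.DataFrame, rng: np.random.Generator):
    """Drop founder haplotypes through the pedigree; return a DosageMatrix.

    Founder haplotype alleles are Bernoulli(founder_maf) draws; variants
    with ``ld_with`` set copy their partner's founder haplotype column, so
    the pair is in perfect LD (r = 1).  Each offspring inherits one whole
    haplotype from each parent (no recombination within the simulated
    region), which keeps Mendelian transmission and LD exact.
    """
    from .variants import DosageMatrix

    order = ped.topological_order()
    idx = {i: k for k, i in enumerate(order)}
    par = ped.parents()
    n, m = len(order), len(panel)
    maf = panel["founder_maf"].to_numpy(dtype=float)
    if (maf <= 0).any() or (maf > 0.5).any():
        raise ValueError("founder MAFs must lie in (0, 0.5]")
    hap = np.zeros((n, 2, m), dtype=np.int8)
    free = panel["ld_with"].isna().to_numpy()
    for i in order:
        a = idx[i]
        f, mo = par[i]
        if f is None:
            hap[a, :, free] = (
                rng.random((free.sum(), 2)) < maf[free][:, None]
            ).astype(np.int8)
        else:
            hap[a, 0] = hap[idx[f], rng.integers(2)]
            hap[a, 1] = hap[idx[mo], rng.integers(2)]
    # perfect-LD copies share the partner's haplotype assignment
    if (~free).any():
        col = {v: j for j, v in enumerate(panel["id"])}
        for j in np.flatnonzero(~free):
            hap[:, :, j] = hap[:, :, col[panel["ld_with"].iloc[j]]]
    g = hap.sum(axis=1).astype(float)
    # back to pedigree row order
    perm = np.array([idx[i] for i in ped.ids])
    meta = panel[["chrom", "pos", "id"]].copy()
    meta["allele"] = "A"
    dm = DosageMatrix(g[perm], ped.ids, meta)
    anno = panel[["id", "is_nonsynonymous", "is_splice"]]
    return dm.attach_annotation(anno).with_maf()


# ---------------------------------------------------------------------------
# traits


def _polygenic(ped: Pedigree, phi: np.ndarray, sigma_g2: float,
               rng: np.random.Generator) -> np.ndarray:
    """Draw gamma ~ N(0, sigma_g2 * Phi) family block by family block."""
    if sigma_g2 == 0:
        return np.zeros(ped.n)
    fam = ped.table["family"].to_numpy()
    gamma = np.empty(ped.n)
    chol_cache: dict[bytes, np.ndarray] = {}
    for f in pd.unique(fam):
        sel = np.flatnonzero(fam == f)
        block = phi[np.ix_(sel, sel)]
        key = block.tobytes()
        if key not in chol_cache:
            # tiny jitter guards exact PSD blocks with zero eigenvalues
            chol_cache[key] = np.linalg.cholesky(
                block + 1e-10 * np.eye(sel.size)
            )
        gamma[sel] = chol_cache[key] @ rng.standard_normal(sel.size)
    return np.sqrt(sigma_g2) * gamma


def simulate_traits(
    ped: Pedigree,
    dm,
    panel: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    phi: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the phenotype table (q1 null trait, dbp, sbp) at baseline.

    Each trait gets independent polygenic and residual draws; variant
    effects come from the panel's ``beta_dbp`` / ``beta_sbp`` columns (the
    q1 trait has none).  Output uses the longitudinal phenotype layout
    (single exam, nobody medicated) so the real-data preparation path can
    consume it unchanged.
    """
    if phi is None:
        phi = kinship_matrix(ped).phi
    n = ped.n
    if dm.n != n or len(panel) != dm.m:
        raise ValueError("pedigree, dosages and panel are misaligned")
    sex_f = (ped.table["sex"].to_numpy() == 2).astype(float)
    age = rng.uniform(*config.age_range, n)
    smoke = (rng.random(n) < config.smoke_prob).astype(float)
    fixed = (
        config.alpha_intercept
        + config.alpha_sex * sex_f
        + config.alpha_age * age
        + config.alpha_smoke * smoke
    )

    def latent(beta: np.ndarray) -> np.ndarray:
        y = fixed + _polygenic(ped, phi, config.sigma_g2, rng)
        y += np.sqrt(config.sigma_e2) * rng.standard_normal(n)
        if beta.any():
            y = y + dm.g @ beta
        return y

    q1 = latent(np.zeros(dm.m))
    dbp = config.dbp_loc + config.dbp_scale * latent(
        panel["beta_dbp"].to_numpy(dtype=float))
    sbp = config.sbp_loc + config.sbp_scale * latent(
        panel["beta_sbp"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "id": ped.ids,
            "exam": 1,
            "age": np.round(age, 1),
            "sex": sex_f,
            "sbp": sbp,
            "dbp": dbp,
            "q1": q1,
            "bp_meds": False,
            "smoke": smoke,
        }
    )


# ---------------------------------------------------------------------------
# replicates and file output


def simulate_replicate(
    config: SimulationConfig,
    panel: pd.DataFrame,
    index: int = 0,
    ped: Pedigree | None = None,
    phi: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Replicate:
    """One full replicate: pedigree (shared or fresh), genotypes, traits."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(index + 1)[-1]
        )
    if ped is None:
        ped = simulate_pedigree(config, rng)
        phi = None
    if phi is None:
        phi = kinship_matrix(ped).phi
    dm = gene_drop(ped, panel, rng)
    pheno = simulate_traits(ped, dm, panel, config, rng, phi=phi)
    truth = {
        "seed": config.seed,
        "replicate": index,
        "sigma_g2": config.sigma_g2,
        "sigma_e2": config.sigma_e2,
        "beta_dbp": dict(zip(panel["id"], panel["beta_dbp"])),
        "beta_sbp": dict(zip(panel["id"], panel["beta_sbp"])),
    }
    return Replicate(index, ped, dm, pheno, truth)


def write_replicate(rep: Replicate, outdir) -> None:
    """Emit the replicate in the same text formats the real-data path reads:
    PED pedigree, dosage TSV, annotation TSV, longitudinal phenotype TSV,
    plus the generating truth as JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t = rep.pedigree.table.copy()
    for c in ("father", "mother"):
        t[c] = t[c].fillna("0")
    t.to_csv(out / "pedigree.ped", sep="\t", header=False, index=False)
    dos = pd.concat(
        [
            rep.dosages.variants[["chrom", "pos", "id", "allele"]],
            pd.DataFrame(rep.dosages.g.T, columns=rep.dosages.sample_ids),
        ],
        axis=1,
    )
    dos.to_csv(out / "dosages.tsv", sep="\t", index=False)
    rep.dosages.variants[["id", "is_nonsynonymous", "is_splice"]].to_csv(
        out / "annotation.tsv", sep="\t", index=False
    )
    rep.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False,
                          na_rep="NA")
    with open(out / "truth.json", "w") as fh:
        json.dump(rep.truth, fh, indent=1, sort_keys=True)
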