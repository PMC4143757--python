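"""Dosage matrices, allele-frequency classification, weights and variant sets.

Variants are classified by sample minor allele frequency: common (MAF > 5%),
rare (0 < MAF <= 5%) or monomorphic (MAF = 0, excluded from all tests).  Rare
variants are aggregated into test units either per gene (nonsynonymous +
splice-site variants within the gene span) or per sliding window (all rare
variants in 4000-bp windows stepped by 2000 bp, annotation-blind).  Each
variant carries a Wu weight, the Beta(1, 25) density at its MAF, which
up-weights the rarest variants.

Coordinates are 1-based inclusive throughout, matching VCF POS.  Dosages are
used as coded in the input (imputed, non-integer dosages included); MAF
folding affects classification and weights only, not the dosage coding, so
the burden direction follows the file's coded allele.  An optional
flip-to-minor switch is available on loading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosageMatrix",
    "VariantSet",
    "Window",
    "read_dosage_tsv",
    "read_dosage_vcf",
    "compute_maf",
    "classify_variants",
    "wu_weights",
    "gene_based_sets",
    "sliding_windows",
    "window_sets",
]

log = logging.getLogger("famrv")

RARE_MAX_MAF = 0.05  # MAF in (0, 0.05] is rare; strictly above is common

VARIANT_META_COLUMNS = ["chrom", "pos", "id", "allele"]


@dataclass
class DosageMatrix:
    """n x m genotype dosages with per-variant metadata.

    ``g[i, j]`` is the expected count (in [0, 2]) of the coded allele of
    variant ``j`` in individual ``i``.  ``variants`` has one row per column
    of ``g`` with at least ``chrom``, ``pos``, ``id`` and, once annotation is
    attached, boolean ``is_nonsynonymous`` / ``is_splice`` columns; ``maf``
    is filled by :func:`compute_maf` via :meth:`with_maf`.
    """

    g: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2:
            raise ValueError("dosage matrix must be 2-d")
        if self.g.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match ids/metadata")
        if np.nanmin(self.g, initial=0.0) < 0 or np.nanmax(self.g, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.g.shape[0]

    @property
    def m(self) -> int:
        return self.g.shape[1]

    def with_maf(self) -> "DosageMatrix":
        """Return self with the ``maf`` metadata column (re)computed."""
        self.variants = self.variants.assign(maf=compute_maf(self.g))
        return self

    def aligned(self, ids: list[str]) -> "DosageMatrix":
        """Reorder rows to ``ids``; every id must be present."""
        pos = {v: k for k, v in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids absent from dosage matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return DosageMatrix(self.g[idx], list(ids), self.variants.copy())

    def attach_annotation(self, anno: pd.DataFrame) -> "DosageMatrix":
        """Join per-variant ``is_nonsynonymous`` / ``is_splice`` flags by id."""
        a = anno.set_index("id")[["is_nonsynonymous", "is_splice"]]
        merged = self.variants.drop(
            columns=[c for c in ("is_nonsynonymous", "is_splice")
                     if c in self.variants], errors="ignore"
        ).join(a, on="id")
        for c in ("is_nonsynonymous", "is_splice"):
            merged[c] = merged[c].fillna(False).astype(bool)
        self.variants = merged
        return self


@dataclass
class VariantSet:
    """One test unit: an ordered selection of variant columns plus weights."""

    label: str
    indices: np.ndarray
    weights: np.ndarray
    chrom: str = ""
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.indices.size == 0:
            raise ValueError(f"variant set {self.label!r} is empty")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError(f"variant set {self.label!r} has duplicate indices")
        if self.weights.shape != self.indices.shape or (self.weights <= 0).any():
            raise ValueError(f"variant set {self.label!r} has invalid weights")

    @property
    def q(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class Window:
    """A 1-based inclusive genomic interval of the sliding-window tiling."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# loading


def read_dosage_tsv(path) -> DosageMatrix:
    """Read a plain dosage TSV: variants x individuals.

    Header: ``chrom  pos  id  allele  <sample1>  <sample2> ...``; one row per
    variant, dosages of the coded ``allele`` in [0, 2].
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in VARIANT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage file missing metadata columns: {missing}")
    samples = [c for c in df.columns if c not in VARIANT_META_COLUMNS]
    g = df[samples].to_numpy(dtype=float).T
    meta = df[VARIANT_META_COLUMNS].copy()
    meta["pos"] = meta["pos"].astype(int)
    return DosageMatrix(g, samples, meta)


def read_dosage_vcf(path, flip_to_minor: bool = False) -> DosageMatrix:
    """Read dosages from a VCF with a ``DS`` FORMAT field (ALT dosage).

    Records without ``DS`` fall back to the hard-genotype ALT count.  With
    ``flip_to_minor`` the coded allele is switched to the minor allele for
    variants whose ALT frequency exceeds 0.5 (dosage becomes ``2 - DS``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(rec.gt_types, dtype=float)  # 0,1,3 = hom-ref,het,hom-alt
            ds = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
        allele = rec.ALT[0] if rec.ALT else "."
        if flip_to_minor and np.nanmean(ds) / 2.0 > 0.5:
            ds = 2.0 - ds
            allele = rec.REF
        rows.append(ds)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        meta.append({"chrom": rec.CHROM, "pos": rec.POS, "id": vid, "allele": allele})
    g = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return DosageMatrix(g, samples, pd.DataFrame(meta, columns=VARIANT_META_COLUMNS))


# ---------------------------------------------------------------------------
# frequencies, classification, weights


def compute_maf(g: np.ndarray) -> np.ndarray:
    """Minor allele frequency per column: fold ``mean(dosage)/2`` onto [0, 0.5]."""
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[1] == 0 or g.shape[0] == 0:
        raise ValueError("cannot compute MAF of an empty dosage column")
    p = g.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def classify_variants(dm: DosageMatrix) -> pd.Series:
    """Label each variant ``common`` (MAF > 5%), ``rare`` (0 < MAF <= 5%) or
    ``monomorphic`` (MAF = 0; excluded from all tests).

    The 5% boundary itself counts as rare.
    """
    if "maf" not in dm.variants:
        dm.with_maf()
    maf = dm.variants["maf"].to_numpy()
    lab = np.where(maf > RARE_MAX_MAF, "common",
                   np.where(maf > 0, "rare", "monomorphic"))
    return pd.Series(lab, index=dm.variants.index, name="class")


def wu_weights(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density at the MAF; defaults give the Wu weights
    ``25 * (1 - maf)**24``."""
    maf = np.asarray(maf, dtype=float)
    if (maf <= 0).any() or (maf > 0.5).any():
        raise ValueError("wu_weights requires MAF in (0, 0.5]")
    return stats.beta.pdf(maf, a, b)


# ---------------------------------------------------------------------------
# set construction


def _rare_mask(dm: DosageMatrix) -> np.ndarray:
    return (classify_variants(dm) == "rare").to_numpy()


def gene_based_sets(dm: DosageMatrix, genes: pd.DataFrame) -> list[VariantSet]:
    """One set per gene: rare nonsynonymous/splice variants in the gene span.

    ``genes`` is a BED-like table with columns ``chrom, start, end, name``
    (1-based inclusive).  Genes with zero qualifying variants are skipped and
    counted in the log.
    """
    if genes["name"].duplicated().any():
        dups = genes.loc[genes["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate gene names: {dups}")
    v = dm.variants
    for c in ("is_nonsynonymous", "is_splice"):
        if c not in v:
            raise ValueError("variant annotation flags missing; attach_annotation first")
    eligible = _rare_mask(dm) & (v["is_nonsynonymous"] | v["is_splice"]).to_numpy()
    out, skipped = [], 0
    for g in genes.itertuples():
        inside = (
            eligible
            & (v["chrom"] == str(g.chrom)).to_numpy()
            & (v["pos"].to_numpy() >= int(g.start))
            & (v["pos"].to_numpy() <= int(g.end))
        )
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            skipped += 1
            continue
        out.append(
            VariantSet(
                label=str(g.name),
                indices=idx,
                weights=wu_weights(v["maf"].to_numpy()[idx]),
                chrom=str(g.chrom),
                span=(int(g.start), int(g.end)),
            )
        )
    if skipped:
        log.info("gene_based_sets: skipped %d/%d genes with no qualifying variants",
                 skipped, len(genes))
    return out


def sliding_windows(
    chrom: str,
    start: int,
    end: int,
    length: int = 4000,
    step: int = 2000,
    anchor: int = 1,
) -> list[Window]:
    """Tile ``[start, end]`` with ``length``-bp windows stepped by ``step``.

    Windows are anchored at ``anchor`` (default: coordinate 1, so the tiling
    phase is deterministic); consecutive windows overlap by ``length - step``
    bp.  Trailing partial windows are dropped; an extent shorter than one
    window yields no windows, with a warning.
    """
    first = anchor + ((max(start, anchor) - anchor) // step) * step
    out = []
    s = first
    while s + length - 1 <= end:
        out.append(Window(str(chrom), s, s + length - 1))
        s += step
    if not out:
        log.warning("sliding_windows: extent %s:%d-%d shorter than one window",
                    chrom, start, end)
    return out


def window_sets(dm: DosageMatrix, windows: list[Window]) -> list[VariantSet]:
    """One set per window: all rare variants with pos in [start, end]
    (bounds inclusive), regardless of annotation.  Empty windows are skipped
    and counted."""
    v = dm.variants
    rare = _rare_mask(dm)
    pos = v["pos"].to_numpy()
    chrom = v["chrom"].to_numpy(dtype=str)
    out, skipped = [], 0
    for w in windows:
        inside = rare & (chrom == w.chrom) & (pos >= w.start) & (pos <= w.end)
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            skipped += 1
            continue
        out.append(
            VariantSet(
                label=w.label,
                indices=idx,
                weights=wu_weights(v["maf"].to_numpy()[idx]),
                chrom=w.chrom,
                span=(w.start, w.end),
            )
        )
    if skipped:
        log.info("window_sets: skipped %d/%d empty windows", skipped, len(windows))
    return out
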