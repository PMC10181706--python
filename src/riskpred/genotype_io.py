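"""Genotype containers, additive encoding, QC filtering, and file I/O.

Genotypes are stored as an ``n x q`` int8 matrix of minor-allele counts:
0 (major homozygote), 1 (heterozygote), 2 (minor homozygote), with
:data:`MISSING` (-1) for no-calls.  Labels are 0 = control, 1 = case.

Supported on-disk formats: VCF 4.x (GT field, diploid), PLINK text
.ped/.map, and a simple internal TSV matrix (header row of SNP ids, one
row per sample: sample_id, label, codes, ``NA`` for missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING: int = -1

__all__ = [
    "MISSING",
    "SNPRecord",
    "QCThresholds",
    "GenotypeDataset",
    "GenotypeError",
    "encode_additive",
    "compute_maf",
    "hwe_test",
    "association_test",
    "qc_filter",
    "balance_classes",
    "stratified_split",
    "impute_mode",
    "read_vcf",
    "read_plink_text",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


class GenotypeError(ValueError):
    """Malformed genotype data (unknown allele, bad record, empty panel)."""


@dataclass
class SNPRecord:
    """Per-SNP metadata; ``maf`` is oriented so that it never exceeds 0.5."""

    snp_id: str
    chromosome: str = "0"
    position: int = 0
    major_allele: str = "A"
    minor_allele: str = "B"
    maf: float = float("nan")
    missing_rate: float = float("nan")
    hwe_p: float = float("nan")


@dataclass(frozen=True)
class QCThresholds:
    """Marker-level QC cutoffs: MAF >= 1%, missingness <= 5%, HWE p >= 1e-3."""

    maf_min: float = 0.01
    missing_max: float = 0.05
    hwe_p_min: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class GenotypeDataset:
    """An additively coded case-control genotype matrix with labels.

    ``provenance`` records the pipeline stages a dataset has passed
    through (e.g. ``("simulated", "qc", "train")``); the evaluation stage
    uses it to refuse test sets that participated in selection/training.
    """

    genotypes: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    snps: list[SNPRecord]
    causal_indices: np.ndarray | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n, q = self.genotypes.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length must equal the number of rows")
        if len(self.snps) != q:
            raise ValueError("snps length must equal the number of columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def with_provenance(self, *stages: str) -> "GenotypeDataset":
        return replace(self, provenance=self.provenance + stages)

    def take_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def take_snps(self, idx: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(list(idx), dtype=int)
        causal = None
        if self.causal_indices is not None:
            pos = {int(j): t for t, j in enumerate(idx)}
            causal = np.array(
                [pos[int(c)] for c in self.causal_indices if int(c) in pos], dtype=int
            )
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            snps=[self.snps[i] for i in idx],
            causal_indices=causal,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.labels, other.labels)
            and self.sample_ids == other.sample_ids
            and self.snp_ids() == other.snp_ids()
        )


# ---------------------------------------------------------------------------
# encoding and per-SNP statistics


def encode_additive(
    genotype_call: str,
    major: str,
    minor: str,
    *,
    missing_tokens: frozenset[str] = frozenset({"00", "..", "NN", "--"}),
    snp_id: str = "?",
    sample_id: str = "?",
) -> int:
    """Count minor-allele copies in a two-allele call string.

    ``major+major`` -> 0, one of each -> 1, ``minor+minor`` -> 2; a
    missing token maps to :data:`MISSING`.
    """
    call = genotype_call.strip().replace("/", "").replace("|", "").replace(" ", "")
    if call in missing_tokens:
        return MISSING
    if len(call) != 2:
        raise GenotypeError(
            f"genotype {genotype_call!r} for SNP {snp_id}, sample {sample_id} "
            "is not a two-allele call"
        )
    code = 0
    for allele in call:
        if allele == minor:
            code += 1
        elif allele != major:
            raise GenotypeError(
                f"allele {allele!r} for SNP {snp_id}, sample {sample_id} "
                f"is neither major {major!r} nor minor {minor!r}"
            )
    return code


def compute_maf(column: np.ndarray) -> tuple[float, bool]:
    """Minor-allele frequency of one coded column.

    Returns ``(maf, flipped)`` where ``flipped`` flags that the raw
    minor-allele dosage frequency exceeded 0.5, i.e. the declared minor
    allele is actually the major one in this cohort.
    """
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise GenotypeError("cannot compute MAF of an all-missing column")
    freq = float(obs.sum()) / (2.0 * obs.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def hwe_test(column: np.ndarray) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Expected genotype counts are ``n*(1-p)^2, 2np(1-p), n*p^2`` with ``p``
    the observed minor-allele frequency.  Degenerate (monomorphic or
    empty) columns return 1.0: equilibrium cannot be rejected.
    """
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0 or np.unique(obs).size < 2:
        return 1.0
    n = obs.size
    counts = np.bincount(obs.astype(np.int64), minlength=3)[:3]
    p = counts @ np.array([0.0, 1.0, 2.0]) / (2.0 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if (expected == 0).any():
        return 1.0
    stat = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1))


def association_test(column: np.ndarray, labels: np.ndarray) -> float:
    """Single-SNP genotypic chi-square association p-value (2x3 table)."""
    column = np.asarray(column)
    labels = np.asarray(labels)
    keep = column != MISSING
    obs, lab = column[keep], labels[keep]
    table = np.zeros((2, 3))
    for y in (0, 1):
        table[y] = np.bincount(obs[lab == y].astype(np.int64), minlength=3)[:3]
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table)[1])


def _annotate(dataset: GenotypeDataset, *, hwe_in_controls: bool = True) -> None:
    """Fill maf/missing_rate/hwe_p on every SNPRecord in place."""
    g = dataset.genotypes
    controls = g[dataset.labels == 0] if hwe_in_controls else g
    if controls.shape[0] == 0:
        controls = g
    for j, rec in enumerate(dataset.snps):
        col = g[:, j]
        rec.missing_rate = float((col == MISSING).mean())
        if (col != MISSING).any():
            rec.maf, flipped = compute_maf(col)
            if flipped:
                rec.major_allele, rec.minor_allele = rec.minor_allele, rec.major_allele
        else:
            rec.maf = 0.0
        rec.hwe_p = hwe_test(controls[:, j])


def qc_filter(
    dataset: GenotypeDataset,
    thresholds: QCThresholds = QCThresholds(),
    *,
    filter_mode: str = "hwe",
) -> tuple[GenotypeDataset, dict[str, list[str]]]:
    """Drop SNPs failing MAF / missingness / p-value cutoffs.

    The p-value filter is, by default, the Hardy-Weinberg test computed in
    controls only (``filter_mode="hwe"``); ``filter_mode="association"``
    applies the same ``p >= hwe_p_min`` rule to a single-SNP case-control
    association test instead.

    Returns the filtered dataset (SNP order preserved) and a report
    mapping reason -> removed SNP ids.
    """
    if filter_mode not in ("hwe", "association"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    _annotate(dataset)
    report: dict[str, list[str]] = {"maf": [], "missing_rate": [], "p_value": []}
    keep: list[int] = []
    for j, rec in enumerate(dataset.snps):
        if filter_mode == "hwe":
            pval = rec.hwe_p
        else:
            pval = association_test(dataset.genotypes[:, j], dataset.labels)
        ok = True
        if rec.maf < thresholds.maf_min:
            report["maf"].append(rec.snp_id)
            ok = False
        if rec.missing_rate > thresholds.missing_max:
            report["missing_rate"].append(rec.snp_id)
            ok = False
        if pval < thresholds.hwe_p_min:
            report["p_value"].append(rec.snp_id)
            ok = False
        if ok:
            keep.append(j)
    if not keep:
        raise GenotypeError("QC filtering removed every SNP")
    return dataset.take_snps(keep).with_provenance("qc"), report


def balance_classes(dataset: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Randomly downsample the majority class to a 50:50 case:control ratio."""
    labels = dataset.labels
    idx_case = np.flatnonzero(labels == 1)
    idx_ctrl = np.flatnonzero(labels == 0)
    if idx_case.size == 0 or idx_ctrl.size == 0:
        raise GenotypeError("both classes must be non-empty to balance")
    rng = np.random.default_rng(seed)
    m = min(idx_case.size, idx_ctrl.size)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(idx_case, size=m, replace=False),
                rng.choice(idx_ctrl, size=m, replace=False),
            ]
        )
    )
    return dataset.take_samples(keep).with_provenance("balanced")


def stratified_split(
    dataset: GenotypeDataset, test_fraction: float = 0.30, seed: int = 0
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Disjoint, label-stratified train/test partition (default 70/30)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction={test_fraction} outside (0, 1)")
    from sklearn.model_selection import train_test_split

    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=dataset.labels,
        random_state=seed,
    )
    train = dataset.take_samples(np.sort(train_idx)).with_provenance("train")
    test = dataset.take_samples(np.sort(test_idx)).with_provenance("test")
    return train, test


def impute_mode(dataset: GenotypeDataset) -> GenotypeDataset:
    """Replace missing codes with the per-SNP most frequent code."""
    g = dataset.genotypes.copy()
    for j in range(g.shape[1]):
        col = g[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        fill = np.bincount(obs.astype(np.int64), minlength=3).argmax() if obs.size else 0
        col[miss] = fill
    return replace(dataset, genotypes=g).with_provenance("imputed")


# ---------------------------------------------------------------------------
# file formats


def _read_labels_file(path: str | Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise GenotypeError(f"{path}:{line_no}: expected 'sample_id label'")
        labels[parts[0]] = int(parts[1])
    return labels


def read_vcf(path: str | Path, labels_path: str | Path) -> GenotypeDataset:
    """Load a diploid VCF; the ALT allele is coded as minor unless the
    cohort frequency says otherwise (then codes are flipped and alleles
    relabelled).  Labels come from a sidecar file of ``sample_id label``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    label_map = _read_labels_file(labels_path)
    try:
        labels = np.array([label_map[s] for s in sample_ids], dtype=np.int8)
    except KeyError as exc:
        raise GenotypeError(f"sample {exc.args[0]!r} missing from label file") from exc

    columns: list[np.ndarray] = []
    snps: list[SNPRecord] = []
    for variant in vcf:
        gts = variant.genotype.array()
        alleles = gts[:, :2]
        codes = np.where((alleles < 0).any(axis=1), MISSING, alleles.sum(axis=1))
        codes = codes.astype(np.int8)
        alt = variant.ALT[0] if variant.ALT else "."
        rec = SNPRecord(
            snp_id=variant.ID or f"{variant.CHROM}:{variant.POS}",
            chromosome=str(variant.CHROM),
            position=int(variant.POS),
            major_allele=variant.REF,
            minor_allele=alt,
        )
        if (codes != MISSING).any():
            maf, flipped = compute_maf(codes)
            if flipped:
                codes = np.where(codes == MISSING, MISSING, 2 - codes).astype(np.int8)
                rec.major_allele, rec.minor_allele = alt, variant.REF
        columns.append(codes)
        snps.append(rec)
    genotypes = np.column_stack(columns) if columns else np.zeros((len(sample_ids), 0), np.int8)
    return GenotypeDataset(genotypes, labels, sample_ids, snps, provenance=("vcf",))


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Load PLINK text .ped/.map.

    .ped columns: FID IID PAT MAT SEX PHENO then two allele columns per
    SNP ("0 0" = missing).  Phenotype 2 -> case, 1 -> control.  The minor
    allele is determined per SNP from the pooled cohort.
    """
    snp_meta: list[tuple[str, str, int]] = []
    for line_no, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeError(f"{map_path}:{line_no}: expected 4 columns")
        snp_meta.append((parts[1], parts[0], int(parts[3])))
    q = len(snp_meta)

    sample_ids: list[str] = []
    labels: list[int] = []
    raw_calls: list[list[tuple[str, str]]] = []
    for line_no, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * q:
            raise GenotypeError(
                f"{ped_path}:{line_no}: expected {6 + 2 * q} columns, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        pheno = parts[5]
        if pheno not in ("1", "2"):
            raise GenotypeError(f"{ped_path}:{line_no}: phenotype {pheno!r} not 1/2")
        labels.append(int(pheno) - 1)
        raw_calls.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(q)]
        )

    n = len(sample_ids)
    genotypes = np.full((n, q), MISSING, dtype=np.int8)
    snps: list[SNPRecord] = []
    for j, (snp_id, chrom, pos) in enumerate(snp_meta):
        alleles = sorted(
            {a for row in raw_calls for a in row[j] if a != "0"}
        )
        if len(alleles) > 2:
            raise GenotypeError(f"SNP {snp_id} has >2 alleles: {alleles}")
        # provisional orientation; flipped below if dosage frequency > 0.5
        major = alleles[0] if alleles else "A"
        minor = alleles[1] if len(alleles) > 1 else major
        for i, row in enumerate(raw_calls):
            a, b = row[j]
            if a == "0" or b == "0":
                continue
            genotypes[i, j] = encode_additive(
                a + b, major, minor, snp_id=snp_id, sample_id=sample_ids[i]
            )
        rec = SNPRecord(snp_id, chrom, pos, major, minor)
        if (genotypes[:, j] != MISSING).any() and len(alleles) > 1:
            _, flipped = compute_maf(genotypes[:, j])
            if flipped:
                col = genotypes[:, j]
                genotypes[:, j] = np.where(col == MISSING, MISSING, 2 - col)
                rec.major_allele, rec.minor_allele = minor, major
        snps.append(rec)
    return GenotypeDataset(
        genotypes, np.array(labels, np.int8), sample_ids, snps, provenance=("ped",)
    )


def read_matrix_tsv(path: str | Path) -> GenotypeDataset:
    """Load the internal TSV matrix: header ``sample_id label <snp ids...>``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise GenotypeError(f"{path}: header must start with 'sample_id\\tlabel'")
    snp_ids = list(df.columns[2:])
    codes = df[snp_ids].to_numpy(dtype=float)
    genotypes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeDataset(
        genotypes,
        df["label"].to_numpy(np.int8),
        df["sample_id"].tolist(),
        [SNPRecord(s) for s in snp_ids],
        provenance=("tsv",),
    )


def write_matrix_tsv(dataset: GenotypeDataset, path: str | Path) -> None:
    codes = dataset.genotypes.astype(float)
    codes[dataset.genotypes == MISSING] = np.nan
    df = pd.DataFrame(codes, columns=dataset.snp_ids())
    df.insert(0, "label", dataset.labels)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")
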