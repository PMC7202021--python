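"""Readers and writers for cytosine reports, SNP tables, phenotypes and matrices.

Cytosine reports follow the per-cytosine tab-separated convention of the
common bisulfite extractors: ``chrom  pos  strand  count_methylated
count_unmethylated  context  [trinucleotide]`` with 1-based positions.
Internally all window arithmetic is 0-based half-open; the conversion happens
at the window-assignment step, not here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import CovarianceStructure, SnpMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CytosineCallSet",
    "PhenotypeTable",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_snp_table",
    "write_snp_table",
    "read_snp_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_matrix",
    "write_matrix",
]

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "meth", "total", "context"]
VALID_CONTEXTS = {"CG", "CHG", "CHH"}
VALID_STRANDS = {"+", "-"}
VALID_ENVIRONMENTS = {"spring", "fall"}
ID_COLUMNS = ["plant_id", "accession_id", "clone_group", "environment"]


@dataclass
class CytosineCallSet:
    """Per-site methylated/total read counts for one sample.

    ``data`` columns: chrom, pos (1-based), strand, meth, total, context.
    Rows are sorted by (chrom, pos); meth <= total and total >= 1 everywhere.
    """

    sample_id: str
    data: pd.DataFrame
    skipped_rows: int = 0

    def __post_init__(self) -> None:
        d = self.data
        missing = [c for c in CYTOSINE_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"cytosine call set missing columns: {missing}")
        d = d.loc[:, CYTOSINE_COLUMNS].copy()
        d["meth"] = d["meth"].astype(int)
        d["total"] = d["total"].astype(int)
        d["pos"] = d["pos"].astype(int)
        if (d["meth"] > d["total"]).any():
            bad = d.index[(d["meth"] > d["total"])][0]
            raise ValueError(f"methylated count exceeds total read count (row index {bad})")
        if (d["total"] < 1).any():
            raise ValueError("zero-coverage sites are not allowed in a call set")
        if (d["meth"] < 0).any():
            raise ValueError("negative methylated counts")
        bad_strand = set(d["strand"].unique()) - VALID_STRANDS
        if bad_strand:
            raise ValueError(f"invalid strand codes: {sorted(bad_strand)}")
        bad_ctx = set(d["context"].unique()) - VALID_CONTEXTS
        if bad_ctx:
            raise ValueError(f"invalid contexts: {sorted(bad_ctx)}")
        d = d.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.data = d

    def __len__(self) -> int:
        return len(self.data)

    def subset_context(self, contexts: set[str]) -> "CytosineCallSet":
        keep = self.data["context"].isin(contexts)
        return CytosineCallSet(self.sample_id, self.data.loc[keep].reset_index(drop=True))


@dataclass
class PhenotypeTable:
    """Plant-level trait table with the plant -> accession -> clone-group maps."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        missing = [c for c in ID_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"phenotype table missing id columns: {missing}")
        d = d.copy()
        for c in ID_COLUMNS:
            d[c] = d[c].astype(str)
        bad_env = set(d["environment"].unique()) - VALID_ENVIRONMENTS
        if bad_env:
            raise ValueError(f"unknown environment labels: {sorted(bad_env)}")
        amb = d.groupby("plant_id")["accession_id"].nunique()
        if (amb > 1).any():
            raise ValueError(f"plants mapped to multiple accessions: {amb[amb > 1].index.tolist()}")
        amb = d.groupby("accession_id")["clone_group"].nunique()
        if (amb > 1).any():
            raise ValueError(
                f"accessions mapped to multiple clone groups: {amb[amb > 1].index.tolist()}"
            )
        counts = d.groupby(["environment", "accession_id"])["plant_id"].nunique()
        lonely = counts[counts < 2]
        if len(lonely):
            warnings.warn(
                f"{len(lonely)} accession/environment cells have <2 plants; "
                "residual variance is weakly informed there",
                stacklevel=2,
            )
        for t in [c for c in d.columns if c not in ID_COLUMNS]:
            d[t] = pd.to_numeric(d[t], errors="coerce")
        self.data = d.reset_index(drop=True)

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def accession_map(self) -> dict[str, str]:
        """plant_id -> accession_id."""
        return dict(zip(self.data["plant_id"], self.data["accession_id"]))

    @property
    def clone_group_map(self) -> dict[str, str]:
        """accession_id -> clone_group."""
        return dict(zip(self.data["accession_id"], self.data["clone_group"]))


def read_cytosine_report(
    path: str | Path,
    context_filter: set[str] = frozenset({"CG"}),
    sample_id: str | None = None,
) -> CytosineCallSet:
    """Read a per-cytosine report; keep requested contexts; total = meth + unmeth.

    Rows with zero total coverage are counted in ``skipped_rows`` rather than
    silently dropped; malformed rows raise with their line number.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows: list[tuple] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position or count") from exc
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            if context not in VALID_CONTEXTS:
                raise ValueError(f"{path}:{lineno}: unknown context {context!r}")
            if context not in context_filter:
                skipped += 1
                continue
            total = meth + unmeth
            if total == 0:
                skipped += 1
                continue
            rows.append((chrom, pos, strand, meth, total, context))
    if not rows:
        warnings.warn(f"{path}: no usable records after filtering", stacklevel=2)
    data = pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)
    return CytosineCallSet(sample_id=sample_id, data=data, skipped_rows=skipped)


def write_cytosine_report(calls: CytosineCallSet, path: str | Path) -> None:
    d = calls.data
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "pos": d["pos"],
            "strand": d["strand"],
            "meth": d["meth"],
            "unmeth": d["total"] - d["meth"],
            "context": d["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_snp_table(path: str | Path) -> SnpMatrix:
    """Labelled TSV of clone-group x SNP codes in {0, 1, NA}.

    Heterozygous-looking codes (anything other than 0/1/NA) are rejected: the
    relatedness construction assumes effectively homozygous lines.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "nan", ""])
    vals = df.to_numpy()
    for v in np.unique(vals[~pd.isna(vals)]):
        try:
            fv = float(v)
        except (TypeError, ValueError):
            raise ValueError(
                f"genotype code {v!r} is not 0/1/NA; heterozygous or diploid-dosage codes "
                "are not supported under the homozygous-line assumption"
            ) from None
        if fv not in (0.0, 1.0):
            raise ValueError(
                f"genotype code {v!r} is not 0/1/NA; heterozygous or diploid-dosage codes "
                "are not supported under the homozygous-line assumption"
            )
    return SnpMatrix(df.astype(float))


def write_snp_table(snps: SnpMatrix, path: str | Path) -> None:
    df = snps.genotypes.copy()
    df.to_csv(path, sep="\t", na_rep="NA")


def read_snp_vcf(path: str | Path) -> SnpMatrix:
    """Read homozygous biallelic genotypes from a VCF (samples = clone groups).

    0/0 -> 0, 1/1 -> 1, ./. -> missing; heterozygous calls and multi-allelic
    sites raise, matching the homozygous-line assumption of the TSV dialect.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"{variant.CHROM}:{variant.POS}: multi-allelic site not supported")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gts = np.asarray(variant.gt_types, dtype=float)
        if np.any(gts == 1):
            raise ValueError(
                f"{variant.CHROM}:{variant.POS}: heterozygous call; the relatedness model "
                "assumes effectively homozygous lines"
            )
        col = np.where(gts == 0, 0.0, np.where(gts == 3, 1.0, np.nan))
        snp_ids.append(f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    vcf.close()
    if not columns:
        raise ValueError(f"{path}: no variant records")
    df = pd.DataFrame(np.column_stack(columns), index=samples, columns=snp_ids)
    return SnpMatrix(df)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, index=False)


def read_matrix(path: str | Path, expect_symmetric: bool = False, kind: str = "genomic"):
    """Read a labelled TSV matrix; symmetric matrices come back as structures.

    With ``expect_symmetric`` the row/column labels must agree and the result
    is a :class:`~extgen.relatedness.CovarianceStructure`; otherwise a plain
    DataFrame is returned.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not expect_symmetric:
        return df
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels differ; not a symmetric structure")
    return CovarianceStructure(values=df.to_numpy(dtype=float), labels=list(df.index.astype(str)), kind=kind)


def write_matrix(obj, path: str | Path) -> None:
    if isinstance(obj, CovarianceStructure):
        obj.to_frame().to_csv(path, sep="\t")
    else:
        pd.DataFrame(obj).to_csv(path, sep="\t")
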