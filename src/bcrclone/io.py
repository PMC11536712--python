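"""Reading/writing external formats, variant filtering and data-derived
hyperparameters.

Count matrices are accepted in MatrixMarket triplet convention (variants x
cells, companion one-per-line label files, 1-based on disk) or as dense TSV;
BCR chains arrive as a CSV of per-cell heavy/light sequences (or a
pre-concatenated FASTA keyed by barcode); the input clone-genotype matrix is
a 0/1 TSV with variant-id rows and clone columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .model import (
    MISSING_CODE,
    Hyperparams,
    ModelData,
    decode_sequences,
    encode_sequences,
)

logger = logging.getLogger("bcrclone")

THETA0_RATIO = 0.002
THETA_I_RATIO = 0.45
#: prior weight of *agreement* with the input genotype call
KAPPA_AGREEMENT_RATIO = 0.8
DEFAULT_G = 0.01
DEFAULT_ALPHA0_PRIOR = (1.0, 1.0)
DEFAULT_MIN_NU_MAGNITUDE = 10.0


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class VariantReadData:
    """Alternate (A) and total (D) UMI counts, variants x cells."""

    alt_counts: np.ndarray
    total_counts: np.ndarray
    variant_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self):
        self.alt_counts = np.asarray(self.alt_counts)
        self.total_counts = np.asarray(self.total_counts)
        a, d = self.alt_counts, self.total_counts
        if a.shape != d.shape:
            raise ValueError("alt and total matrices differ in shape")
        if len(self.variant_ids) != a.shape[0]:
            raise ValueError("variant label count does not match matrix rows")
        if len(self.cell_barcodes) != a.shape[1]:
            raise ValueError("cell barcode count does not match matrix columns")
        if np.any(a < 0) or np.any(d < 0):
            raise ValueError("negative read counts")
        bad = np.argwhere(a > d)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                "alt exceeds total at variant "
                f"{self.variant_ids[i]!r}, cell {self.cell_barcodes[j]!r}"
            )

    @property
    def n_variants(self) -> int:
        return self.alt_counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.alt_counts.shape[1]


@dataclass
class BcrAlignment:
    """Variable BCR positions of the retained cells, integer-coded."""

    nucleotides: np.ndarray  # (M, L) int8, 0..3 = ACGT, 4 = missing
    position_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self):
        self.nucleotides = np.asarray(self.nucleotides, dtype=np.int8)
        if self.nucleotides.shape != (len(self.cell_barcodes), len(self.position_ids)):
            raise ValueError("BCR matrix shape does not match labels")

    def sequences(self) -> list[str]:
        return decode_sequences(self.nucleotides)


@dataclass
class VariantTable:
    """Per-variant annotations used by the selection filters."""

    records: pd.DataFrame  # columns: id, tumour_vaf, normal_vaf, is_snv, somatic_call

    REQUIRED = ("id", "tumour_vaf", "normal_vaf", "is_snv", "somatic_call")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        vafs = self.records[["tumour_vaf", "normal_vaf"]].to_numpy(dtype=float)
        if np.any((vafs < 0) | (vafs > 1)):
            raise ValueError("VAFs must lie in [0, 1]")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def _read_labels(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _read_matrix(path) -> np.ndarray:
    """Load one count matrix: MatrixMarket triplet or dense TSV."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("%%MatrixMarket"):
        mat = scipy.io.mmread(path)
        coo = scipy.sparse.coo_array(mat)
        pairs = np.stack([coo.row, coo.col])
        n_unique = np.unique(pairs, axis=1).shape[1]
        if n_unique < len(coo.data):
            logger.warning(
                "%s: %d duplicate triplet entries summed",
                path.name,
                len(coo.data) - n_unique,
            )
        coo.sum_duplicates()
        return np.asarray(coo.todense())
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def read_counts(alt_path, total_path, variants_path, barcodes_path) -> VariantReadData:
    """Read the A/D pair with its label files into a validated container."""
    alt = _read_matrix(alt_path)
    total = _read_matrix(total_path)
    variant_ids = _read_labels(variants_path)
    barcodes = _read_labels(barcodes_path)
    if alt.shape != (len(variant_ids), len(barcodes)):
        raise ValueError(
            f"matrix shape {alt.shape} does not match "
            f"{len(variant_ids)} variants x {len(barcodes)} barcodes"
        )
    return VariantReadData(
        alt_counts=alt.astype(np.int64),
        total_counts=total.astype(np.int64),
        variant_ids=variant_ids,
        cell_barcodes=barcodes,
    )


def write_counts(reads: VariantReadData, alt_path, total_path, variants_path, barcodes_path):
    scipy.io.mmwrite(str(alt_path), scipy.sparse.coo_array(reads.alt_counts))
    scipy.io.mmwrite(str(total_path), scipy.sparse.coo_array(reads.total_counts))
    Path(variants_path).write_text("\n".join(reads.variant_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(reads.cell_barcodes) + "\n")


# ---------------------------------------------------------------------------
# BCR sequences
# ---------------------------------------------------------------------------


def read_bcr(
    path,
    barcode_col: str = "barcode",
    heavy_col: str = "heavy_seq",
    light_col: str = "light_seq",
) -> tuple[list[str], list[str]]:
    """Per-cell concatenated heavy+light sequences from a CSV.

    Cells missing either chain are dropped and the count reported.
    """
    df = pd.read_csv(path, dtype=str)
    for col in (barcode_col, heavy_col, light_col):
        if col not in df.columns:
            raise ValueError(f"BCR table lacks column {col!r}")
    complete = df[heavy_col].notna() & df[light_col].notna()
    complete &= (df[heavy_col].fillna("").str.len() > 0) & (
        df[light_col].fillna("").str.len() > 0
    )
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropped %d cells lacking a complete heavy+light BCR", dropped)
    df = df[complete]
    barcodes = df[barcode_col].tolist()
    seqs = (df[heavy_col] + df[light_col]).tolist()
    return barcodes, seqs


def read_bcr_fasta(path) -> tuple[list[str], list[str]]:
    """Pre-concatenated sequences keyed by barcode from a FASTA file."""
    from Bio import SeqIO

    barcodes, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        barcodes.append(rec.id)
        seqs.append(str(rec.seq))
    return barcodes, seqs


def select_bcr_positions(
    barcodes: list[str], seqs: list[str], missing: str = "N"
) -> BcrAlignment:
    """Keep exactly the columns where at least one cell differs from the
    column consensus (majority nucleotide over observed cells, ties broken
    in fixed A<C<G<T order); missing symbols are ignored in the vote."""
    codes = encode_sequences(seqs, missing=missing)
    M, L = codes.shape
    keep, ids = [], []
    for l in range(L):
        col = codes[:, l]
        obs = col[col < MISSING_CODE]
        if obs.size == 0:
            continue
        consensus = np.bincount(obs, minlength=4).argmax()
        if np.any(obs != consensus):
            keep.append(l)
            ids.append(f"pos{l}")
    if not keep:
        raise ValueError(
            "no variable BCR positions: every cell matches the consensus, "
            "so the BCR sequences carry no clustering information"
        )
    return BcrAlignment(
        nucleotides=codes[:, keep], position_ids=ids, cell_barcodes=list(barcodes)
    )


# ---------------------------------------------------------------------------
# variant table and filters
# ---------------------------------------------------------------------------


def read_variant_table(path) -> VariantTable:
    df = pd.read_csv(path, sep="\t")
    df["is_snv"] = df["is_snv"].astype(bool)
    df["somatic_call"] = df["somatic_call"].astype(bool)
    return VariantTable(records=df)


def read_variant_table_vcf(
    path, tumour_vaf_key: str = "TVAF", normal_vaf_key: str = "NVAF",
    somatic_key: str = "SOMATIC",
) -> VariantTable:
    """Variant table from a VCF whose INFO carries tumour/normal VAFs."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        alt = v.ALT[0] if v.ALT else ""
        rows.append(
            {
                "id": f"{v.CHROM}:{v.POS}:{v.REF}:{alt}",
                "tumour_vaf": float(v.INFO.get(tumour_vaf_key, 0.0)),
                "normal_vaf": float(v.INFO.get(normal_vaf_key, 0.0)),
                "is_snv": len(v.REF) == 1 and len(alt) == 1,
                "somatic_call": bool(v.INFO.get(somatic_key) is not None),
            }
        )
    return VariantTable(records=pd.DataFrame(rows))


def filter_variants(
    table: VariantTable, reads: VariantReadData, fold: float = 3.0
) -> tuple[VariantReadData, list[str]]:
    """Variant-selection rule applied to the count matrices.

    Keeps single-nucleotide variants that are either somatic-called or show
    more than a ``fold``-fold increase of the alternate-allele frequency in
    the tumour over the normal sample, and that have at least one alternate
    read across the cells.
    """
    rec = table.records.set_index("id")
    missing = [v for v in reads.variant_ids if v not in rec.index]
    if missing:
        raise ValueError(f"variant table lacks entries for {missing[:5]} ...")
    keep = []
    for i, vid in enumerate(reads.variant_ids):
        row = rec.loc[vid]
        germline_ok = row["tumour_vaf"] > fold * row["normal_vaf"]
        if not bool(row["is_snv"]):
            continue
        if not (bool(row["somatic_call"]) or germline_ok):
            continue
        if reads.alt_counts[i].sum() < 1:
            continue
        keep.append(i)
    if not keep:
        logger.warning("variant filtering removed every variant")
        return (
            VariantReadData(
                alt_counts=np.zeros((0, reads.n_cells), dtype=np.int64),
                total_counts=np.zeros((0, reads.n_cells), dtype=np.int64),
                variant_ids=[],
                cell_barcodes=reads.cell_barcodes,
            ),
            [],
        )
    kept_ids = [reads.variant_ids[i] for i in keep]
    return (
        VariantReadData(
            alt_counts=reads.alt_counts[keep],
            total_counts=reads.total_counts[keep],
            variant_ids=kept_ids,
            cell_barcodes=reads.cell_barcodes,
        ),
        kept_ids,
    )


# ---------------------------------------------------------------------------
# genotype matrix, cell alignment, assembly
# ---------------------------------------------------------------------------


def read_genotype_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Binary clone-genotype TSV (variant rows, clone columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    omega = df.to_numpy()
    if not np.all(np.isin(omega, [0, 1])):
        raise ValueError("genotype matrix entries must be 0/1")
    return omega.astype(np.int8), list(df.index.astype(str)), list(df.columns.astype(str))


def write_genotype_matrix(path, omega, variant_ids, clone_ids):
    pd.DataFrame(omega, index=variant_ids, columns=clone_ids).to_csv(path, sep="\t")


def intersect_cells(
    reads: VariantReadData, bcr: BcrAlignment
) -> tuple[VariantReadData, BcrAlignment]:
    """Restrict both containers to barcodes present in each, in read order."""
    bcr_index = {b: j for j, b in enumerate(bcr.cell_barcodes)}
    keep_r, keep_b = [], []
    for j, b in enumerate(reads.cell_barcodes):
        if b in bcr_index:
            keep_r.append(j)
            keep_b.append(bcr_index[b])
    dropped = (reads.n_cells - len(keep_r)) + (len(bcr.cell_barcodes) - len(keep_b))
    if dropped:
        logger.info("dropped %d cells absent from one of the inputs", dropped)
    if not keep_r:
        raise ValueError("no cells shared between count matrices and BCR table")
    reads2 = VariantReadData(
        alt_counts=reads.alt_counts[:, keep_r],
        total_counts=reads.total_counts[:, keep_r],
        variant_ids=reads.variant_ids,
        cell_barcodes=[reads.cell_barcodes[j] for j in keep_r],
    )
    bcr2 = BcrAlignment(
        nucleotides=bcr.nucleotides[keep_b],
        position_ids=bcr.position_ids,
        cell_barcodes=[bcr.cell_barcodes[j] for j in keep_b],
    )
    return reads2, bcr2


def build_model_data(
    reads: VariantReadData,
    bcr: BcrAlignment,
    omega: np.ndarray,
    clone_ids: list[str] | None = None,
) -> ModelData:
    if reads.cell_barcodes != bcr.cell_barcodes:
        raise ValueError("cell barcodes differ; call intersect_cells first")
    omega = np.asarray(omega, dtype=np.int8)
    if clone_ids is None:
        clone_ids = [f"clone{k + 1}" for k in range(omega.shape[1])]
    return ModelData(
        alt=reads.alt_counts,
        total=reads.total_counts,
        omega=omega,
        x=bcr.nucleotides,
        variant_ids=reads.variant_ids,
        cell_barcodes=reads.cell_barcodes,
        clone_ids=clone_ids,
        position_ids=bcr.position_ids,
    )


# ---------------------------------------------------------------------------
# data-dependent hyperparameters
# ---------------------------------------------------------------------------


def derive_hyperparams(
    reads: VariantReadData,
    n_clones: int,
    n_positions: int,
    min_nu_magnitude: float = DEFAULT_MIN_NU_MAGNITUDE,
    g_strength: float = DEFAULT_G,
) -> Hyperparams:
    """Priors scaled to the data, following the model-application defaults.

    * theta0 ~ Beta with mean 0.002 and magnitude equal to the total number
      of reference reads in the sample;
    * theta_i ~ Beta with mean 0.45 and magnitude equal to the total number
      of alternate reads of variant i (floored at ``min_nu_magnitude`` when
      a variant has none);
    * xi ~ Beta with magnitude N*K weighted 0.8 toward agreement with the
      input genotype call;
    * flat Dirichlet(0.01) profile prior; Gamma(1, 1) concentration prior.
    """
    if reads.n_variants == 0:
        raise ValueError("cannot derive hyperparameters from an empty matrix")
    total_ref = float((reads.total_counts - reads.alt_counts).sum())
    mag0 = total_ref if total_ref > 0 else min_nu_magnitude
    nu0 = (THETA0_RATIO * mag0, (1.0 - THETA0_RATIO) * mag0)
    alt_sums = reads.alt_counts.sum(axis=1).astype(float)
    mags = np.where(alt_sums > 0, alt_sums, min_nu_magnitude)
    nu_i = np.column_stack([THETA_I_RATIO * mags, (1.0 - THETA_I_RATIO) * mags])
    mag_k = float(reads.n_variants * n_clones)
    kappa = ((1.0 - KAPPA_AGREEMENT_RATIO) * mag_k, KAPPA_AGREEMENT_RATIO * mag_k)
    g = np.full((n_positions, 4), g_strength)
    return Hyperparams(
        kappa=kappa, nu0=nu0, nu_i=nu_i, g=g, alpha0_prior=DEFAULT_ALPHA0_PRIOR
    )


def write_fit_result(result, outdir, data: ModelData):
    """Serialise a fit: cell-clone posterior TSV, MAP assignment and
    hypercluster TSV, corrected clone-genotype TSV, diagnostics JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clone_ids = data.clone_ids or [
        f"clone{k + 1}" for k in range(data.n_clones)
    ]
    pd.DataFrame(
        result.assignment_probs, index=data.cell_barcodes, columns=clone_ids
    ).to_csv(outdir / "assignment_probs.tsv", sep="\t")
    pd.DataFrame(
        {
            "map_clone": result.map_assignment,
            "map_clone_id": [clone_ids[k] for k in result.map_assignment],
            "ml_hypercluster": result.ml_hyperclustering,
        },
        index=pd.Index(data.cell_barcodes, name="barcode"),
    ).to_csv(outdir / "assignment.tsv", sep="\t")
    pd.DataFrame(
        result.map_genotypes, index=data.variant_ids, columns=clone_ids
    ).to_csv(outdir / "genotypes.tsv", sep="\t")
    diag = {
        "selected_chain": result.selected_chain,
        "mpsrf": result.mpsrf,
        "converged": result.converged,
        "chain_summaries": result.chain_summaries,
    }
    (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2) + "\n")


def write_manifest(path, **entries):
    """JSON manifest recording filters, seeds and parameters of a run."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(entries, indent=2, default=_default) + "\n")
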