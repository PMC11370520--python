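"""Scoring engine: weight tables, genotypes, harmonization, and PRS algebra.

A polygenic risk score (PRS) is the weighted sum over variants of per-variant
effect weights multiplied by the dosage of the effect allele, ``s_i = sum_v
w_v * d_iv``.  Before scoring, the weight table must be *harmonized* against
the genotype orientation: when the table's effect/other alleles are swapped
relative to the genotyped orientation the effect-allele dosage is ``2 - d``.
Strand-ambiguous variants (A/T and C/G) cannot be oriented from alleles alone
and are dropped by default.

Scores move through three adjustment states: ``raw`` -> ``pc_adjusted``
(residual from an OLS regression on genotype principal components, removing
population-structure signal) -> ``standardized`` (zero mean, unit SD on the
defining cohort, with the (mean, SD) stored so the transform replays on
held-out samples).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ContractError,
    HarmonizationError,
    ScoreFileFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

#: PGS Catalog scoring-file column names mapped to internal names.
_PGS_COLUMNS = {
    "rsID": "variant_id",
    "chr_name": "chr",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "weight",
}
_INTERNAL_COLUMNS = list(_PGS_COLUMNS.values())


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class VariantWeightTable:
    """A per-SNP scoring table (one component PRS, or a collapsed meta-PRS).

    ``df`` columns: variant_id, chr, pos (1-based), effect_allele,
    other_allele, weight.  ``metadata`` holds the '#'-prefixed header lines of
    a PGS Catalog scoring file (preserved on round trip) plus free-form
    provenance added by the pipeline.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _INTERNAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ScoreFileFormatError(f"weight table missing column(s): {missing}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicated variant_id: {dup!r}")
        for col in ("effect_allele", "other_allele"):
            bad = ~self.df[col].isin(list(_VALID_ALLELES))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"non-ACGT allele in column {col!r} at row {row}: "
                    f"{self.df[col].iloc[row]!r}"
                )
        same = self.df["effect_allele"] == self.df["other_allele"]
        if same.any():
            row = int(np.flatnonzero(same.to_numpy())[0])
            raise ValidationError(f"effect_allele == other_allele at row {row}")
        w = self.df["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite weight(s) in table")
        self.df["weight"] = w

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def harmonized(self) -> bool:
        return "geno_index" in self.df.columns

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.df.to_csv(index=False).encode())
        return h.hexdigest()


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with variant metadata.

    ``dosages`` is samples x variants, values in [0, 2] of the *counted*
    allele (``allele2``); NaN marks missing.  ``variants`` columns:
    variant_id, chr, pos, allele1 (other), allele2 (counted), af (counted
    allele frequency).
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            out_of_range = (self.dosages < 0) | (self.dosages > 2)
        if np.any(out_of_range):
            raise ValidationError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        if "af" not in self.variants.columns:
            self.variants["af"] = np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # -- I/O ---------------------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        """Write a plain-text dosage matrix (variants as rows)."""
        meta = self.variants[["variant_id", "chr", "pos", "allele1", "allele2", "af"]]
        body = pd.DataFrame(
            self.dosages.T, columns=self.sample_ids, index=meta.index
        )
        pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        meta_cols = ["variant_id", "chr", "pos", "allele1", "allele2", "af"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise ScoreFileFormatError(f"dosage TSV missing column(s): {missing}")
        sample_ids = np.array([c for c in df.columns if c not in meta_cols])
        return cls(
            sample_ids=sample_ids,
            variants=df[meta_cols].copy(),
            dosages=df[sample_ids].to_numpy(dtype=float).T,
        )

    def to_vcf(self, path) -> None:
        """Write an uncompressed VCF with a DS (dosage) FORMAT field."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Estimated alternate allele dosage">\n'
            )
            for c in sorted(self.variants["chr"].astype(str).unique()):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.sample_ids))
                + "\n"
            )
            for j, row in self.variants.iterrows():
                ds = [
                    "." if np.isnan(d) else f"{d:.4g}" for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{row['chr']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                    f"{row['allele1']}\t{row['allele2']}\t.\t.\t.\tDS\t"
                    + "\t".join(ds)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read dosages from a VCF; prefers the DS FORMAT field, falls back to GT."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        sample_ids = np.array(vcf.samples)
        meta, rows = [], []
        for var in vcf:
            try:
                ds = np.asarray(var.format("DS"), dtype=float).ravel()
            except (KeyError, TypeError, ValueError):
                gts = np.asarray(var.gt_types, dtype=float)
                ds = np.where(gts == 2, np.nan, np.where(gts == 3, 2.0, gts))
            meta.append(
                (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS,
                 var.REF, var.ALT[0] if var.ALT else "N")
            )
            rows.append(ds)
        variants = pd.DataFrame(
            meta, columns=["variant_id", "chr", "pos", "allele1", "allele2"]
        )
        return cls(sample_ids=sample_ids, variants=variants,
                   dosages=np.array(rows, dtype=float).T)


@dataclass
class ScoreVector:
    """A per-sample score with its provenance and adjustment state."""

    sample_ids: np.ndarray
    values: np.ndarray
    state: str = "raw"  # raw | pc_adjusted | standardized
    provenance: dict = field(default_factory=dict)
    mean_: float | None = None  # stored by standardize()
    sd_: float | None = None
    pc_theta_: np.ndarray | None = None  # stored by adjust_for_pcs()

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.sample_ids.shape:
            raise ContractError("score values and sample_ids length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class HarmonizationReport:
    n_table: int
    matched: int
    flipped: int
    dropped_ambiguous: int
    unmatched: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Scoring-file I/O (PGS Catalog layout)
# ---------------------------------------------------------------------------


def read_score_file(path) -> VariantWeightTable:
    """Read a PGS Catalog scoring file ('#' metadata lines, tab-separated body).

    Mandatory body columns: ``effect_allele``, ``effect_weight``, and a
    variant identifier (``rsID``, with ``chr_name``/``chr_position`` used as a
    positional fallback).  Unknown metadata lines are preserved verbatim.
    """
    header_lines: list[str] = []
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line.rstrip("\n"))
            else:
                body.write(line)
    body.seek(0)
    try:
        raw = pd.read_csv(body, sep="\t", dtype={"chr_name": str, "rsID": str})
    except pd.errors.EmptyDataError as exc:
        raise ScoreFileFormatError(f"{path}: empty scoring file") from exc

    for col in ("effect_allele", "effect_weight"):
        if col not in raw.columns:
            raise ScoreFileFormatError(f"{path}: missing mandatory column {col!r}")
    if "other_allele" not in raw.columns:
        raise ScoreFileFormatError(f"{path}: missing mandatory column 'other_allele'")
    if "rsID" not in raw.columns:
        if not {"chr_name", "chr_position"} <= set(raw.columns):
            raise ScoreFileFormatError(
                f"{path}: need 'rsID' or 'chr_name'+'chr_position' to identify variants"
            )
        raw["rsID"] = raw["chr_name"].astype(str) + ":" + raw["chr_position"].astype(str)
    if "chr_name" not in raw.columns:
        raw["chr_name"] = "NA"
    if "chr_position" not in raw.columns:
        raw["chr_position"] = 0

    df = raw.rename(columns=_PGS_COLUMNS)[_INTERNAL_COLUMNS]
    df["chr"] = df["chr"].astype(str)
    df["pos"] = df["pos"].astype(int)
    return VariantWeightTable(df=df, metadata={"header_lines": header_lines})


def write_score_file(table: VariantWeightTable, path) -> None:
    """Write a table in PGS Catalog scoring layout; read∘write is the identity."""
    inv = {v: k for k, v in _PGS_COLUMNS.items()}
    out = table.df[_INTERNAL_COLUMNS].rename(columns=inv)
    with open(path, "w") as fh:
        for line in table.metadata.get("header_lines", []):
            fh.write(line + "\n")
        # repr-precision floats so a round trip reproduces weights exactly
        out.to_csv(fh, sep="\t", index=False, float_format=None)


# ---------------------------------------------------------------------------
# Harmonization and scoring
# ---------------------------------------------------------------------------


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _AMBIGUOUS_PAIRS


def harmonize(
    table: VariantWeightTable,
    geno: GenotypeMatrix,
    ambiguous_policy: str = "drop",
) -> tuple[VariantWeightTable, HarmonizationReport]:
    """Match a weight table to genotype orientation.

    Matching precedence: ``variant_id`` first, then ``chr:pos`` with an
    identical allele set.  Variants whose effect/other alleles are swapped
    relative to the counted genotype allele are marked ``flipped`` (scored as
    ``2 - d``).  Strand-ambiguous variants (A/T, C/G) are dropped under the
    default policy and kept oriented-as-matched under ``keep``.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ContractError(f"unknown ambiguous_policy {ambiguous_policy!r}")

    gv = geno.variants
    t = table.df
    # primary match on variant_id
    idx_by_id = pd.Series(np.arange(len(gv)), index=gv["variant_id"])
    j = idx_by_id.reindex(t["variant_id"]).to_numpy(dtype=float)
    # positional fallback for the unmatched (requires identical allele set)
    miss = np.isnan(j)
    if miss.any():
        gkey = gv["chr"].astype(str) + ":" + gv["pos"].astype(int).astype(str)
        idx_by_pos = pd.Series(np.arange(len(gv)), index=gkey)
        idx_by_pos = idx_by_pos[~idx_by_pos.index.duplicated()]
        tkey = t["chr"].astype(str) + ":" + t["pos"].astype(int).astype(str)
        j2 = idx_by_pos.reindex(tkey[miss]).to_numpy(dtype=float)
        ok = ~np.isnan(j2)
        cand = j2[ok].astype(int)
        same_set = (
            (gv["allele1"].to_numpy()[cand] == t.loc[miss, "effect_allele"].to_numpy()[ok])
            & (gv["allele2"].to_numpy()[cand] == t.loc[miss, "other_allele"].to_numpy()[ok])
        ) | (
            (gv["allele2"].to_numpy()[cand] == t.loc[miss, "effect_allele"].to_numpy()[ok])
            & (gv["allele1"].to_numpy()[cand] == t.loc[miss, "other_allele"].to_numpy()[ok])
        )
        j2[np.flatnonzero(ok)[~same_set]] = np.nan
        j[miss] = j2

    found = ~np.isnan(j)
    ji = np.where(found, j, 0).astype(int)
    a1 = gv["allele1"].to_numpy()[ji]
    a2 = gv["allele2"].to_numpy()[ji]
    ea = t["effect_allele"].to_numpy()
    oa = t["other_allele"].to_numpy()
    direct = found & (ea == a2) & (oa == a1)
    flip = found & (ea == a1) & (oa == a2)
    ambiguous = np.array([_is_ambiguous(e, o) for e, o in zip(ea, oa)])
    drop_amb = ambiguous & (direct | flip) if ambiguous_policy == "drop" else np.zeros(len(t), bool)
    keep = (direct | flip) & ~drop_amb

    matched = int(keep.sum())
    flipped = int((flip & keep).sum())
    dropped = int(drop_amb.sum())
    unmatched = int(len(t) - matched - dropped)
    if matched == 0:
        raise HarmonizationError("no variants could be harmonized against genotypes")

    hdf = pd.DataFrame(
        {
            "variant_id": t["variant_id"].to_numpy()[keep],
            "chr": t["chr"].astype(str).to_numpy()[keep],
            "pos": t["pos"].astype(int).to_numpy()[keep],
            "effect_allele": ea[keep],
            "other_allele": oa[keep],
            "weight": t["weight"].to_numpy(dtype=float)[keep],
            "geno_index": ji[keep],
            "flipped": flip[keep],
        }
    )
    out = VariantWeightTable(df=hdf, metadata=dict(table.metadata))
    report = HarmonizationReport(
        n_table=table.n_variants,
        matched=matched,
        flipped=flipped,
        dropped_ambiguous=dropped,
        unmatched=unmatched,
    )
    return out, report


def compute_prs(
    geno: GenotypeMatrix,
    table: VariantWeightTable,
    missing_policy: str = "impute",
) -> ScoreVector:
    """Score samples: ``s = sum_v w_v * d_v`` over the harmonized variants.

    Missing dosages are imputed as twice the effect-allele frequency
    (``missing_policy='impute'``, the default) or propagate NaN to the
    sample's score (``'exclude'``).
    """
    if not table.harmonized:
        raise ContractError("compute_prs requires a harmonized weight table")
    if missing_policy not in ("impute", "exclude"):
        raise ContractError(f"unknown missing_policy {missing_policy!r}")

    idx = table.df["geno_index"].to_numpy(dtype=int)
    flip = table.df["flipped"].to_numpy(dtype=bool)
    w = table.df["weight"].to_numpy(dtype=float)
    D = geno.dosages[:, idx]
    # effect-allele dosage: counted dosage, or its complement when flipped
    Deff = np.where(flip[None, :], 2.0 - D, D)
    if missing_policy == "impute":
        af = geno.variants["af"].to_numpy(dtype=float)[idx]
        eaf = np.where(flip, 1.0 - af, af)
        Deff = np.where(np.isnan(Deff), 2.0 * eaf[None, :], Deff)
    values = Deff @ w
    return ScoreVector(
        sample_ids=geno.sample_ids,
        values=values,
        state="raw",
        provenance={
            "source": table.metadata.get("name", "weight_table"),
            "n_variants": int(len(w)),
            "missing_policy": missing_policy,
        },
    )


def blend_scores(
    scores: Sequence[ScoreVector], blend_weights: Sequence[float]
) -> ScoreVector:
    """Fixed-weight linear blend of standardized component scores."""
    if len(scores) != len(blend_weights):
        raise ContractError("blend: scores and weights length mismatch")
    if len(scores) == 0:
        raise ContractError("blend: no scores given")
    n = len(scores[0])
    for s in scores:
        if len(s) != n or not np.array_equal(s.sample_ids, scores[0].sample_ids):
            raise ContractError("blend: scores are not aligned on the same samples")
        if s.state != "standardized":
            raise ContractError("blend: all input scores must be standardized")
    values = np.zeros(n)
    for s, w in zip(scores, blend_weights):
        values += float(w) * s.values
    return ScoreVector(
        sample_ids=scores[0].sample_ids,
        values=values,
        state="raw",
        provenance={
            "blend_of": [s.provenance.get("source", "?") for s in scores],
            "blend_weights": [float(w) for w in blend_weights],
        },
    )


def adjust_for_pcs(score: ScoreVector, pcs: np.ndarray) -> ScoreVector:
    """Residualize a score on genotype principal components (OLS, intercept).

    Stores the projection coefficients ``theta`` (intercept first) so the
    collapse stage can keep its bookkeeping.  Collinear PC columns are handled
    by a minimum-norm least-squares solve with a logged warning.
    """
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[0] != len(score):
        raise ContractError("PC matrix rows must align with score samples")
    X = np.column_stack([np.ones(len(score)), pcs])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "PC matrix is rank-deficient (rank %d < %d); using minimum-norm solve",
            rank, X.shape[1],
        )
    theta, *_ = np.linalg.lstsq(X, score.values, rcond=None)
    resid = score.values - X @ theta
    return replace(
        score,
        values=resid,
        state="pc_adjusted",
        provenance={**score.provenance, "pc_adjusted": True, "n_pcs": pcs.shape[1]},
        pc_theta_=theta,
    )


def standardize(
    score: ScoreVector, mean: float | None = None, sd: float | None = None
) -> ScoreVector:
    """Scale a score to mean 0, SD 1 (sample SD, ddof=1) on the defining cohort.

    Pass stored ``(mean, sd)`` to replay a training-cohort transform on
    held-out samples.
    """
    if mean is None or sd is None:
        mean = float(np.mean(score.values))
        sd = float(np.std(score.values, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ContractError("standardize: score has zero (or undefined) variance")
    return replace(
        score,
        values=(score.values - mean) / sd,
        state="standardized",
        provenance={**score.provenance, "standardized": True},
        mean_=float(mean),
        sd_=float(sd),
    )
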