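"""Founder haplotype dosages for multiparental mouse panels.

A Collaborative Cross (CC) strain genome is a homozygous mosaic of the eight
founder haplotypes (AJ, B6, 129, NOD, NZO, CAST, PWK, WSB).  At every genotyped
locus a strain carries an expected dosage of each founder haplotype; the eight
dosages sum to two (one per chromosome copy), and for a fully inbred strain the
vector is one-hot times two.  These dosage vectors are the genetic predictors
``x_i`` of the per-locus association model.

This module provides the dosage container, the merging of adjacent redundant
loci (identical founder mosaics across all strains produce identical tests, so
they are collapsed by averaging), and imputation of biallelic variant dosages
from founder haplotype dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOUNDERS: tuple[str, ...] = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
N_FOUNDERS = len(FOUNDERS)

#: loci within this distance (bp) of a trait anchor count as "local"
LOCAL_WINDOW_BP = 10_000_000

_DOSAGE_SUM_TOL = 1e-8


class FounderDosageMatrix:
    """Strains x loci x 8 founder haplotype dosages with a locus map.

    Parameters
    ----------
    dosages:
        Array of shape ``(n_strains, n_loci, 8)``; every strain/locus 8-vector
        must sum to 2 within ``1e-8``.
    strains:
        Strain identifiers, length ``n_strains``.
    locus_map:
        DataFrame with columns ``locus_id``, ``chrom``, ``pos_bp`` (1-based),
        optionally ``members`` (comma-joined provenance of merged loci),
        sorted by (chrom, pos_bp).
    """

    def __init__(self, dosages: np.ndarray, strains: list[str], locus_map: pd.DataFrame):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 3 or dosages.shape[2] != N_FOUNDERS:
            raise ValueError("dosages must have shape (n_strains, n_loci, 8)")
        if dosages.shape[0] != len(strains):
            raise ValueError("strain list does not match dosage array")
        if dosages.shape[1] != len(locus_map):
            raise ValueError("locus map does not match dosage array")
        sums = dosages.sum(axis=2)
        if not np.allclose(sums, 2.0, atol=_DOSAGE_SUM_TOL):
            raise ValueError("every strain-locus dosage vector must sum to 2")
        locus_map = locus_map.reset_index(drop=True)
        if locus_map["locus_id"].duplicated().any():
            raise ValueError("locus ids must be unique")
        self.dosages = dosages
        self.strains = list(strains)
        self.locus_map = locus_map
        self._locus_index = {lid: i for i, lid in enumerate(locus_map["locus_id"])}

    # ------------------------------------------------------------------ basic
    @property
    def n_strains(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def locus_position(self, locus_id: str) -> tuple[str, float]:
        i = self._locus_index[locus_id]
        row = self.locus_map.iloc[i]
        return str(row["chrom"]), float(row["pos_bp"])

    def locus_X(self, locus_id: str) -> np.ndarray:
        """Dosage design block (n_strains x 8) for one locus."""
        return self.dosages[:, self._locus_index[locus_id], :]

    def locus_iloc(self, locus_id: str) -> int:
        return self._locus_index[locus_id]

    def loci_on(self, chrom: str) -> np.ndarray:
        """Integer indices of all loci on a chromosome, in map order."""
        return np.flatnonzero(self.locus_map["chrom"].to_numpy() == chrom)

    def local_window(self, chrom: str, anchor_bp: float,
                     radius_bp: float = LOCAL_WINDOW_BP) -> np.ndarray:
        """Indices of loci within ``radius_bp`` (inclusive) of an anchor."""
        on = self.loci_on(chrom)
        pos = self.locus_map["pos_bp"].to_numpy()[on]
        return on[np.abs(pos - anchor_bp) <= radius_bp]

    # --------------------------------------------------------------------- io
    def to_tsv(self, dosage_path, map_path=None) -> None:
        """Write long-format dosage TSV (strain, locus_id, chrom, pos_bp, 8 founders)."""
        n_s, n_l, _ = self.dosages.shape
        rec = {
            "strain": np.repeat(self.strains, n_l),
            "locus_id": np.tile(self.locus_map["locus_id"].to_numpy(), n_s),
            "chrom": np.tile(self.locus_map["chrom"].to_numpy(), n_s),
            "pos_bp": np.tile(self.locus_map["pos_bp"].to_numpy(), n_s),
        }
        flat = self.dosages.reshape(n_s * n_l, N_FOUNDERS)
        for j, f in enumerate(FOUNDERS):
            rec[f] = flat[:, j]
        pd.DataFrame(rec).to_csv(dosage_path, sep="\t", index=False)
        if map_path is not None:
            self.locus_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path) -> "FounderDosageMatrix":
        df = pd.read_csv(dosage_path, sep="\t")
        strains = list(dict.fromkeys(df["strain"]))
        first = df[df["strain"] == strains[0]]
        locus_map = first[["locus_id", "chrom", "pos_bp"]].reset_index(drop=True)
        locus_map["chrom"] = locus_map["chrom"].astype(str)
        n_l = len(locus_map)
        dosages = (
            df[list(FOUNDERS)].to_numpy(float).reshape(len(strains), n_l, N_FOUNDERS)
        )
        return cls(dosages, strains, locus_map)


@dataclass
class VariantTable:
    """Biallelic variants with per-founder alleles (0/1, NaN = missing call)."""

    table: pd.DataFrame  # variant_id, chrom, pos_bp, 8 founder allele columns

    def alleles(self) -> np.ndarray:
        return self.table[list(FOUNDERS)].to_numpy(float)


# ---------------------------------------------------------------------- merge

def merge_similar_loci(fdm: FounderDosageMatrix, fraction: float = 0.1,
                       max_distance: float = 2.0) -> FounderDosageMatrix:
    """Collapse runs of adjacent loci whose founder mosaics agree in all strains.

    Greedy left-to-right within each chromosome: the next locus joins the
    current group iff, for *every* strain, the L2 distance between its
    8-vector and the group's running average is at most
    ``fraction * max_distance`` (default threshold 0.2).  Merged dosages are
    elementwise means; the merged position is the mean of member positions;
    the merged id is the first member's id and provenance is recorded in a
    ``members`` column.
    """
    threshold = fraction * max_distance
    if threshold <= 0:  # merging disabled; pass the map through
        lm = fdm.locus_map.copy()
        if "members" not in lm.columns:
            lm["members"] = lm["locus_id"]
        return FounderDosageMatrix(fdm.dosages.copy(), fdm.strains, lm)
    lm = fdm.locus_map
    out_dos: list[np.ndarray] = []
    out_rows: list[dict] = []
    for chrom in dict.fromkeys(lm["chrom"]):
        idx = fdm.loci_on(str(chrom))
        group: list[int] = []
        running: np.ndarray | None = None

        def flush():
            if not group:
                return
            member_rows = lm.iloc[group]
            out_dos.append(fdm.dosages[:, group, :].mean(axis=1))
            out_rows.append({
                "locus_id": member_rows.iloc[0]["locus_id"],
                "chrom": chrom,
                "pos_bp": float(member_rows["pos_bp"].mean()),
                "members": ",".join(member_rows["locus_id"].astype(str)),
            })

        for i in idx:
            vec = fdm.dosages[:, i, :]
            if running is None:
                group, running = [i], vec.copy()
                continue
            dist = np.sqrt(((vec - running) ** 2).sum(axis=1)).max()
            if dist <= threshold:
                group.append(i)
                running = fdm.dosages[:, group, :].mean(axis=1)
            else:
                flush()
                group, running = [i], vec.copy()
        flush()
    dosages = np.stack(out_dos, axis=1)
    return FounderDosageMatrix(dosages, fdm.strains, pd.DataFrame(out_rows))


# -------------------------------------------------------------------- variants

def impute_variant_dosage(alleles: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-strain minor-allele dosage from founder alleles and haplotype dosages.

    ``dosage_i = sum_f x_{i,f} * allele_f``; alleles must be complete (no NaN).
    """
    alleles = np.asarray(alleles, dtype=float)
    if np.isnan(alleles).any():
        raise ValueError("variant has a missing founder allele; exclude upstream")
    return X @ alleles


def _nearest_locus_idx(fdm: FounderDosageMatrix, chrom: str, pos_bp: float) -> int | None:
    on = fdm.loci_on(chrom)
    if on.size == 0:
        return None
    pos = fdm.locus_map["pos_bp"].to_numpy()[on]
    return int(on[np.argmin(np.abs(pos - pos_bp))])


def impute_variant_dosages(variants: VariantTable,
                           fdm: FounderDosageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Impute dosages for all variants at their nearest mapped locus.

    Returns ``(dosage matrix n_strains x n_variants, valid mask)``; variants
    with a missing founder call or no locus on their chromosome are invalid
    (dosage columns are NaN).
    """
    A = variants.alleles()
    n_v = len(variants.table)
    out = np.full((fdm.n_strains, n_v), np.nan)
    valid = np.zeros(n_v, dtype=bool)
    for v in range(n_v):
        row = variants.table.iloc[v]
        if np.isnan(A[v]).any():
            continue
        li = _nearest_locus_idx(fdm, str(row["chrom"]), float(row["pos_bp"]))
        if li is None:
            continue
        out[:, v] = fdm.dosages[:, li, :] @ A[v]
        valid[v] = True
    return out, valid


def maf_filter(variants: VariantTable, fdm: FounderDosageMatrix,
               min_maf: float = 0.1) -> tuple[VariantTable, np.ndarray]:
    """Drop variants with imputed MAF <= ``min_maf`` or any missing founder call.

    Returns the filtered table and the imputed dosage matrix for kept variants.
    """
    dos, valid = impute_variant_dosages(variants, fdm)
    freq = np.full(len(variants.table), np.nan)
    freq[valid] = dos[:, valid].mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = valid & (maf > min_maf)
    return VariantTable(variants.table.loc[keep].reset_index(drop=True)), dos[:, keep]
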