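"""Genotype containers and PLINK 1 binary (.bed/.bim/.fam) input/output.

Genotypes are held as a dense ``float64`` matrix of minor-allele dosages
(samples x variants) with ``NaN`` marking missing calls.  The variant map
(``variant_id``, ``chrom``, ``pos``, ``a1``, ``a2``) and the sample roster
(``fid``, ``iid``) travel with the matrix so that subsetting keeps
everything aligned.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit SNP-major PLINK codes -> A1 (minor-allele) dosage
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2"]


def _as_genotype_matrix(genotypes) -> np.ndarray:
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x variants)")
    finite = g[np.isfinite(g)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype values must be 0, 1, 2 or missing (NaN)")
    return g


@dataclasses.dataclass
class GenotypeDataset:
    """Additive-coded diallelic genotypes with variant map and sample roster.

    Parameters
    ----------
    genotypes : ndarray, shape (n_samples, n_variants)
        Minor-allele (A1) dosages in {0, 1, 2}; NaN for missing calls.
    variants : DataFrame
        One row per variant with columns ``variant_id, chrom, pos, a1, a2``.
    samples : DataFrame
        One row per sample with at least columns ``fid, iid``.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = _as_genotype_matrix(self.genotypes)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant map lacks columns {missing_cols}")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in variant map")
        if self.samples["iid"].duplicated().any():
            raise ValueError("duplicate sample ids (iid)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.samples["iid"]

    @property
    def variant_ids(self) -> pd.Series:
        return self.variants["variant_id"]

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["variant_id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"unknown variant id: {variant_id!r}")
        return int(hits[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self.variant_index(variant_id)]

    # -- subsetting -----------------------------------------------------
    def select_samples(self, index) -> "GenotypeDataset":
        """Subset by positional or boolean sample index, keeping alignment."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            self.genotypes[index, :].copy(),
            self.variants.copy(),
            self.samples.iloc[index].copy(),
        )

    def select_variants(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            self.genotypes[:, index].copy(),
            self.variants.iloc[index].copy(),
            self.samples.copy(),
        )

    def add_variant(
        self, variant_id: str, values, chrom: int, pos: int, a1: str = "A", a2: str = "G"
    ) -> "GenotypeDataset":
        """Return a new dataset with one appended variant column."""
        if variant_id in set(self.variants["variant_id"]):
            raise ValueError(f"variant id already present: {variant_id!r}")
        col = _as_genotype_matrix(np.asarray(values, dtype=float).reshape(-1, 1))
        if col.shape[0] != self.n_samples:
            raise ValueError("manual variant length does not match sample count")
        row = pd.DataFrame(
            [[variant_id, chrom, pos, a1, a2]], columns=VARIANT_COLUMNS
        )
        return GenotypeDataset(
            np.hstack([self.genotypes, col]),
            pd.concat([self.variants, row], ignore_index=True),
            self.samples.copy(),
        )

    def drop_variant(self, variant_id: str) -> "GenotypeDataset":
        j = self.variant_index(variant_id)
        keep = np.ones(self.n_variants, dtype=bool)
        keep[j] = False
        return self.select_variants(keep)

    # -- per-variant summaries ------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """A1 allele frequency per variant over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=1)


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O (v1.0, SNP-major)
# ---------------------------------------------------------------------------

def _pack_variant(dosages: np.ndarray) -> np.ndarray:
    """Pack one variant's dosages into PLINK 2-bit codes (4 samples/byte)."""
    n = dosages.shape[0]
    codes = np.full(n, 0b01, dtype=np.uint8)  # missing
    codes[dosages == 2.0] = 0b00
    codes[dosages == 1.0] = 0b10
    codes[dosages == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    return (
        quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    ).astype(np.uint8)


def write_plink(dataset: GenotypeDataset, prefix) -> dict:
    """Write ``prefix``.bed/.bim/.fam (PLINK 1 binary, SNP-major).

    A1 is the dosage-counted (minor) allele, as in the additive coding of
    the in-memory matrix.  Returns the mapping of written file paths.
    """
    if dataset.n_samples == 0 or dataset.n_variants == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    payload = bytearray(_BED_MAGIC)
    for j in range(dataset.n_variants):
        payload.extend(_pack_variant(dataset.genotypes[:, j]).tobytes())
    bed = prefix.with_suffix(".bed")
    bed.write_bytes(bytes(payload))

    bim = prefix.with_suffix(".bim")
    v = dataset.variants
    bim_df = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "variant_id": v["variant_id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim_df.to_csv(bim, sep="\t", header=False, index=False)

    fam = prefix.with_suffix(".fam")
    s = dataset.samples
    fam_df = pd.DataFrame(
        {
            "fid": s["fid"],
            "iid": s["iid"],
            "father": 0,
            "mother": 0,
            "sex": s["sex"] if "sex" in s.columns else 0,
            "phenotype": -9,
        }
    )
    fam_df.to_csv(fam, sep="\t", header=False, index=False)
    return {"bed": bed, "bim": bim, "fam": fam}


def read_plink(prefix) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset written in SNP-major order."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"variant_id": str, "a1": str, "a2": str},
    )
    raw = np.frombuffer(prefix.with_suffix(".bed").read_bytes(), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file (bad magic bytes)")
    n, m = len(fam), len(bim)
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * m:
        raise ValueError(".bed payload size does not match .bim/.fam dimensions")
    body = body.reshape(m, bytes_per_variant)
    geno = np.empty((n, m), dtype=float)
    shifts = (2 * (np.arange(n) % 4)).astype(np.uint8)
    byte_idx = np.arange(n) // 4
    for j in range(m):
        codes = (body[j, byte_idx] >> shifts) & 0b11
        geno[:, j] = _DOSAGE_FOR_CODE[codes]
    variants = bim[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeDataset(geno, variants, fam[["fid", "iid", "sex"]].copy())
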