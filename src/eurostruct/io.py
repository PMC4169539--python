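"""Genotype, sample-panel and geographic-panel I/O.

The in-memory container is :class:`GenotypeDataset`: an integer dosage matrix
(samples x SNPs, counting copies of the A1/"alt" allele, PLINK1 convention)
plus sample identifiers, per-sample population labels and a SNP map. Missing
genotypes are held as the integer sentinel :data:`MISSING`, never NaN; the
matrix is converted to floating point only inside numeric operations.

Two on-disk formats are supported and round-trip exactly:

* PLINK1 binary (``.bed``/``.bim``/``.fam``), SNP-major dialect only.
* A tab-delimited text trio (``<prefix>.genotypes.tsv`` with samples in rows
  and SNP ids as header, ``<prefix>.snps.tsv`` with the SNP map).

Population labels live in a sidecar panel TSV (``sample_id<TAB>population``)
rather than being squeezed into the .fam FID column; ``population_from_fid``
restores the lazier convention for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype in the integer dosage matrix.
MISSING: int = -1

#: Token used for missing dosages in the text genotype format.
_NA_TOKEN = "NA"

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# PLINK1 .bed two-bit codes (value of the bit pair, low bits first within a
# byte): 0b00 hom A1, 0b01 missing, 0b10 het, 0b11 hom A2. Dosage counts A1.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Malformed file contents (bad magic bytes, bad header, bad values)."""


class IntegrityError(ValueError):
    """Files are individually well formed but mutually inconsistent."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identifier, physical location and allele pair."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position_bp must be >= 1")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are equal")


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with sample and marker metadata.

    ``dosages[i, j]`` counts copies of ``snps[j].allele_alt`` carried by
    ``sample_ids[i]`` and is one of {0, 1, 2, MISSING}.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snps: list[SnpRecord]
    populations: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, s = self.dosages.shape
        if n != len(self.sample_ids):
            raise IntegrityError("row count != number of sample ids")
        if n != len(self.populations):
            raise IntegrityError("population labels must cover every sample")
        if s != len(self.snps):
            raise IntegrityError("column count != number of SNP records")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        ids = [r.snp_id for r in self.snps]
        if len(set(ids)) != s:
            raise ValueError("snp ids must be unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or the missing sentinel")
        if any(p == "." for p in self.populations):
            raise ValueError("'.' is not allowed as a population name")

    # -- conveniences -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.snps]

    def population_indices(self) -> dict[str, np.ndarray]:
        """Row indices per population label, in first-appearance order."""
        out: dict[str, np.ndarray] = {}
        pops = np.asarray(self.populations)
        for p in dict.fromkeys(self.populations):
            out[p] = np.flatnonzero(pops == p)
        return out

    def take_samples(self, rows: Sequence[int]) -> "GenotypeDataset":
        rows = np.asarray(rows, dtype=int)
        return GenotypeDataset(
            self.dosages[rows],
            [self.sample_ids[i] for i in rows],
            list(self.snps),
            [self.populations[i] for i in rows],
        )

    def take_snps(self, cols: Sequence[int]) -> "GenotypeDataset":
        cols = np.asarray(cols, dtype=int)
        return GenotypeDataset(
            self.dosages[:, cols],
            list(self.sample_ids),
            [self.snps[j] for j in cols],
            list(self.populations),
        )

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeDataset":
        """Subset to the given SNP ids, in the given order."""
        index = {r.snp_id: j for j, r in enumerate(self.snps)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"SNPs absent from dataset: {missing[:10]}")
        return self.take_snps([index[s] for s in snp_ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.sample_ids == other.sample_ids
            and self.snps == other.snps
            and self.populations == other.populations
        )


@dataclass
class GeoPanel:
    """Geographic centre (degrees) of each population."""

    table: pd.DataFrame  # index: population; columns: latitude_deg, longitude_deg

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate population rows: {dup}")
        lat = t["latitude_deg"].to_numpy(float)
        lon = t["longitude_deg"].to_numpy(float)
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")

    @classmethod
    def from_dict(cls, coords: dict[str, tuple[float, float]]) -> "GeoPanel":
        """Build from ``{population: (latitude_deg, longitude_deg)}``."""
        t = pd.DataFrame.from_dict(coords, orient="index", columns=["latitude_deg", "longitude_deg"])
        t.index.name = "population"
        return cls(t)

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    def subset(self, pops: Sequence[str]) -> "GeoPanel":
        return GeoPanel(self.table.loc[list(pops)].copy())

    def latlon(self, pop: str) -> tuple[float, float]:
        row = self.table.loc[pop]
        return float(row["latitude_deg"]), float(row["longitude_deg"])


# ---------------------------------------------------------------------------
# PLINK1 binary
# ---------------------------------------------------------------------------

def _byte_decode_table() -> np.ndarray:
    """256 x 4 lookup: byte value -> dosages of the four packed genotypes."""
    table = np.empty((256, 4), dtype=np.int8)
    for b in range(256):
        for s in range(4):
            table[b, s] = _CODE_TO_DOSAGE[(b >> (2 * s)) & 0b11]
    return table


_DECODE = _byte_decode_table()


def _read_bed(path: Path, n_samples: int, n_snps: int) -> np.ndarray:
    raw = path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{path}: not a PLINK1 .bed file (bad magic bytes)")
    if raw[2] != _BED_SNP_MAJOR:
        raise IntegrityError(f"{path}: individual-major .bed is not supported")
    bytes_per_snp = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * n_snps:
        raise IntegrityError(
            f"{path}: payload of {payload.size} bytes does not match "
            f"{n_samples} samples x {n_snps} SNPs from .fam/.bim"
        )
    if n_snps == 0:
        return np.empty((n_samples, 0), dtype=np.int8)
    per_snp = payload.reshape(n_snps, bytes_per_snp)
    dosages = _DECODE[per_snp].reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    return np.ascontiguousarray(dosages.T)


def _write_bed(path: Path, dosages: np.ndarray) -> None:
    n_samples, n_snps = dosages.shape
    bytes_per_snp = (n_samples + 3) // 4
    codes = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    code_of = np.zeros(4, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_CODE.items():
        code_of[dose] = code  # MISSING == -1 wraps to index 3; dosage 3 unused
    codes[:, :n_samples] = code_of[dosages.T.astype(np.int64) % 4]
    shifted = codes.reshape(n_snps, bytes_per_snp, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = np.bitwise_or.reduce(shifted, axis=2).astype(np.uint8)
    path.write_bytes(_BED_MAGIC + bytes([_BED_SNP_MAJOR]) + packed.tobytes())


def _read_bim(path: Path) -> list[SnpRecord]:
    records: list[SnpRecord] = []
    with path.open() as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, snp_id, _cm, pos, a1, a2 = line.split()
            records.append(SnpRecord(snp_id, chrom, int(pos), allele_ref=a2, allele_alt=a1))
    return records


def _write_bim(path: Path, snps: Sequence[SnpRecord]) -> None:
    with path.open("w") as fh:
        for r in snps:
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\t{r.allele_alt}\t{r.allele_ref}\n")


# ---------------------------------------------------------------------------
# Panel files
# ---------------------------------------------------------------------------

def read_panel(path: Path | str) -> pd.Series:
    """Read a sample panel TSV (``sample_id<TAB>population``) to a Series."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"sample_id", "population"}
    if not expected.issubset(t.columns):
        raise FormatError(f"{path}: panel must have columns {sorted(expected)}")
    if t["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in panel")
    return t.set_index("sample_id")["population"]


def write_panel(path: Path | str, sample_ids: Sequence[str], populations: Sequence[str]) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "population": list(populations)}).to_csv(
        path, sep="\t", index=False
    )


def read_geo_panel(path: Path | str) -> GeoPanel:
    """Read a population geographic-centre TSV.

    Expected columns: ``population``, ``latitude_deg``, ``longitude_deg``
    (``lat``/``lon`` accepted as aliases). Coordinates are validated against
    [-90, 90] / [-180, 180] and populations must be unique.
    """
    t = pd.read_csv(path, sep="\t")
    t = t.rename(columns={"lat": "latitude_deg", "lon": "longitude_deg"})
    needed = {"population", "latitude_deg", "longitude_deg"}
    if not needed.issubset(t.columns):
        raise FormatError(f"{path}: geo panel must have columns {sorted(needed)}")
    return GeoPanel(t.set_index("population")[["latitude_deg", "longitude_deg"]])


def write_geo_panel(path: Path | str, geo: GeoPanel) -> None:
    geo.table.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dataset read/write
# ---------------------------------------------------------------------------

def read_genotypes(
    prefix: Path | str,
    format: str = "plink1",
    panel: Path | str | None = None,
    population_from_fid: bool = False,
) -> GenotypeDataset:
    """Read a genotype dataset.

    Parameters
    ----------
    prefix:
        Path prefix; ``<prefix>.bed/.bim/.fam`` for ``format="plink1"``,
        ``<prefix>.genotypes.tsv`` and ``<prefix>.snps.tsv`` for ``"tsv"``.
    panel:
        Optional sample-panel TSV providing population labels. Defaults to
        ``<prefix>.panel.tsv`` when that file exists.
    population_from_fid:
        For PLINK input without a panel, take population labels from the .fam
        FID column.
    """
    prefix = Path(prefix)
    if format == "plink1":
        fam = pd.read_csv(
            Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
            names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
        )
        sample_ids = fam["iid"].tolist()
        snps = _read_bim(Path(str(prefix) + ".bim"))
        dosages = _read_bed(Path(str(prefix) + ".bed"), len(sample_ids), len(snps))
        default_pops = fam["fid"].tolist() if population_from_fid else ["0"] * len(sample_ids)
    elif format == "tsv":
        geno = pd.read_csv(
            Path(str(prefix) + ".genotypes.tsv"), sep="\t", index_col=0,
            na_values=[_NA_TOKEN], keep_default_na=False,
        )
        snp_table = pd.read_csv(Path(str(prefix) + ".snps.tsv"), sep="\t", dtype=str)
        snps = [
            SnpRecord(r.snp_id, r.chromosome, int(r.position_bp), r.allele_ref, r.allele_alt)
            for r in snp_table.itertuples()
        ]
        if list(geno.columns) != [r.snp_id for r in snps]:
            raise IntegrityError(f"{prefix}: genotype header and SNP map disagree")
        sample_ids = [str(s) for s in geno.index]
        dosages = geno.to_numpy(float)
        dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
        default_pops = ["0"] * len(sample_ids)
    else:
        raise ValueError(f"unknown format {format!r}")

    panel_path = Path(panel) if panel is not None else Path(str(prefix) + ".panel.tsv")
    if panel_path.exists():
        labels = read_panel(panel_path)
        try:
            populations = [str(labels[s]) for s in sample_ids]
        except KeyError as e:
            raise IntegrityError(f"panel is missing sample {e.args[0]!r}") from None
    else:
        populations = default_pops
    return GenotypeDataset(dosages, sample_ids, snps, populations)


def write_genotypes(ds: GenotypeDataset, prefix: Path | str, format: str = "plink1") -> None:
    """Write a dataset (including its sample panel) under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink1":
        _write_bed(Path(str(prefix) + ".bed"), ds.dosages)
        _write_bim(Path(str(prefix) + ".bim"), ds.snps)
        with Path(str(prefix) + ".fam").open("w") as fh:
            for sid, pop in zip(ds.sample_ids, ds.populations):
                fh.write(f"{pop}\t{sid}\t0\t0\t0\t-9\n")
    elif format == "tsv":
        geno = pd.DataFrame(
            ds.dosages.astype(object), index=pd.Index(ds.sample_ids, name="sample_id"),
            columns=ds.snp_ids,
        )
        geno = geno.where(ds.dosages != MISSING, _NA_TOKEN)
        geno.to_csv(Path(str(prefix) + ".genotypes.tsv"), sep="\t")
        pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id,
                    "chromosome": r.chromosome,
                    "position_bp": r.position_bp,
                    "allele_ref": r.allele_ref,
                    "allele_alt": r.allele_alt,
                }
                for r in ds.snps
            ]
        ).to_csv(Path(str(prefix) + ".snps.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    write_panel(Path(str(prefix) + ".panel.tsv"), ds.sample_ids, ds.populations)
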