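"""Domain types and file I/O for amplicon genotype and clinical tables.

An *amplicon* is a PCR-amplified locus harbouring an insertion/deletion
polymorphism; its alleles are distinguished by fragment length in base
pairs.  A genotype call is an unordered pair of allele lengths, or missing.
Clinical tables carry the DAS28 components (28-joint tender/swollen counts,
patient global VAS, CRP) or a precomputed DAS28 per visit, plus the
TNF-alpha inhibitor the patient started.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Amplicon",
    "GenotypeCall",
    "ClinicalRecord",
    "Cohort",
    "GenotypingRate",
    "read_panel",
    "read_genotype_table",
    "write_genotype_table",
    "read_clinical_table",
    "write_clinical_table",
    "genotyping_rate",
]

PROTOCOLS = ("sequencing", "fragment_analysis")
DRUGS = ("infliximab", "adalimumab", "etanercept")
VISITS = ("baseline", "week26")

#: default token marking a missing genotype call / absent clinical value
MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class Amplicon:
    """A genotyped INDEL locus with its observed allele-length set."""

    amplicon_id: str
    gene: str = ""
    chromosome: str = ""
    protocol: str = "sequencing"
    alleles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"{self.amplicon_id}: allele set must be non-empty")
        if any((not isinstance(a, int)) or a <= 0 for a in self.alleles):
            raise ValueError(
                f"{self.amplicon_id}: allele lengths must be positive integers"
            )
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"{self.amplicon_id}: unknown protocol {self.protocol!r}")
        object.__setattr__(self, "alleles", tuple(sorted(set(self.alleles))))

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def length_range(self) -> int:
        """Difference between the longest and shortest allele (bp)."""
        return self.alleles[-1] - self.alleles[0]


@dataclass(frozen=True)
class GenotypeCall:
    """Unordered pair of allele lengths for one patient at one amplicon.

    ``allele_pair`` is None when the call is missing.  Pairs are normalized
    to (min, max) so that 271/288 and 288/271 compare equal.
    """

    patient_id: str
    amplicon_id: str
    allele_pair: Optional[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.allele_pair is not None:
            a, b = self.allele_pair
            object.__setattr__(self, "allele_pair", (min(a, b), max(a, b)))

    @property
    def is_missing(self) -> bool:
        return self.allele_pair is None


@dataclass(frozen=True)
class ClinicalRecord:
    """One clinical visit: DAS28 components and/or the composite score."""

    patient_id: str
    visit: str
    tjc28: Optional[int] = None
    sjc28: Optional[int] = None
    patient_global: Optional[float] = None
    crp: Optional[float] = None
    das28: Optional[float] = None
    drug: Optional[str] = None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"{self.patient_id}: unknown visit {self.visit!r}")
        if self.tjc28 is not None and not 0 <= self.tjc28 <= 28:
            raise ValueError(f"{self.patient_id}: tjc28={self.tjc28} outside [0, 28]")
        if self.sjc28 is not None and not 0 <= self.sjc28 <= 28:
            raise ValueError(f"{self.patient_id}: sjc28={self.sjc28} outside [0, 28]")
        if self.patient_global is not None and not 0 <= self.patient_global <= 100:
            raise ValueError(
                f"{self.patient_id}: patient_global={self.patient_global} outside [0, 100]"
            )
        if self.crp is not None and self.crp < 0:
            raise ValueError(f"{self.patient_id}: crp must be >= 0")
        if self.das28 is not None and self.das28 < 0:
            raise ValueError(f"{self.patient_id}: das28 must be >= 0")
        if self.drug is not None and self.drug not in DRUGS:
            raise ValueError(f"{self.patient_id}: unknown drug {self.drug!r}")
        if self.das28 is None:
            components = (self.tjc28, self.sjc28, self.patient_global, self.crp)
            if any(c is None for c in components):
                raise ValueError(
                    f"{self.patient_id}/{self.visit}: either das28 or all four "
                    "components (tjc28, sjc28, patient_global, crp) are required"
                )


@dataclass
class Cohort:
    """Panel, genotype calls and clinical visits for one patient cohort.

    ``genotypes`` maps amplicon_id -> {patient_id -> allele pair or None};
    ``clinical`` maps patient_id -> {visit -> ClinicalRecord};
    ``labels`` maps patient_id -> EULAR category and may be derived later.
    """

    amplicons: dict[str, Amplicon] = field(default_factory=dict)
    genotypes: dict[str, dict[str, Optional[tuple[int, int]]]] = field(
        default_factory=dict
    )
    clinical: dict[str, dict[str, ClinicalRecord]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        """All patient ids seen in genotype or clinical tables, sorted."""
        ids = set()
        for calls in self.genotypes.values():
            ids.update(calls)
        ids.update(self.clinical)
        return sorted(ids)

    def calls(self, amplicon_id: str, patients: Optional[Iterable[str]] = None,
              drop_missing: bool = True) -> list[tuple[int, int]]:
        """Non-missing allele pairs at one amplicon, optionally restricted."""
        if amplicon_id not in self.genotypes:
            raise KeyError(f"unknown amplicon {amplicon_id!r}")
        table = self.genotypes[amplicon_id]
        ids = list(table) if patients is None else [p for p in patients if p in table]
        pairs = [table[p] for p in ids]
        if drop_missing:
            return [g for g in pairs if g is not None]
        return pairs


@dataclass(frozen=True)
class GenotypingRate:
    """Fraction of patients successfully genotyped at an amplicon."""

    amplicon_id: str
    n_called: int
    n_patients: int

    @property
    def rate(self) -> float:
        return self.n_called / self.n_patients

    @property
    def below_95(self) -> bool:
        """At least 5% of samples lack a genotype."""
        return self.rate < 0.95

    @property
    def below_90(self) -> bool:
        return self.rate < 0.90

    def __float__(self) -> float:
        return self.rate


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_panel(path) -> list[Amplicon]:
    """Read an amplicon panel TSV.

    Columns: amplicon_id, gene, chromosome, protocol, alleles
    (comma-separated lengths in bp).
    """
    out: list[Amplicon] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            aid = row["amplicon_id"].strip()
            if aid in seen:
                raise ValueError(f"duplicate amplicon_id {aid!r} in panel")
            seen.add(aid)
            alleles = tuple(int(x) for x in row["alleles"].split(",") if x.strip())
            out.append(
                Amplicon(
                    amplicon_id=aid,
                    gene=row.get("gene", "").strip(),
                    chromosome=row.get("chromosome", "").strip(),
                    protocol=row.get("protocol", "sequencing").strip(),
                    alleles=alleles,
                )
            )
    return out


def _parse_cell(cell: str, row_label: str, col: str, alleles: set[int],
                missing_token: str) -> Optional[tuple[int, int]]:
    cell = cell.strip()
    if cell == "" or cell == missing_token:
        return None
    parts = cell.split("/")
    if len(parts) != 2:
        raise ValueError(
            f"malformed genotype cell {cell!r} at row {row_label!r}, column {col!r}"
        )
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(
            f"malformed genotype cell {cell!r} at row {row_label!r}, column {col!r}"
        ) from exc
    for length in (a, b):
        if length not in alleles:
            raise ValueError(
                f"allele {length} at row {row_label!r}, column {col!r} "
                f"is not in the amplicon's allele set"
            )
    return (min(a, b), max(a, b))


def read_genotype_table(path, panel: Iterable[Amplicon],
                        missing_token: str = MISSING_TOKEN) -> Cohort:
    """Read a patient x amplicon genotype TSV into a Cohort.

    The header row is ``patient_id`` followed by amplicon ids; cells are
    "L1/L2" (order-free) or the missing token / empty.
    """
    amplicons = {a.amplicon_id: a for a in panel}
    cohort = Cohort(amplicons=amplicons)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError("genotype table is empty (no header)")
        if header[0] != "patient_id":
            raise ValueError("genotype table must start with a 'patient_id' column")
        amp_cols = header[1:]
        for col in amp_cols:
            if col not in amplicons:
                raise ValueError(f"genotype column {col!r} is not in the panel")
            cohort.genotypes.setdefault(col, {})
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            pid = row[0].strip()
            for col, cell in zip(amp_cols, row[1:]):
                if pid in cohort.genotypes[col]:
                    raise ValueError(
                        f"patient {pid!r} appears more than once for amplicon {col!r}"
                    )
                cohort.genotypes[col][pid] = _parse_cell(
                    cell, pid, col, set(amplicons[col].alleles), missing_token
                )
    return cohort


def write_genotype_table(path, cohort: Cohort,
                         missing_token: str = MISSING_TOKEN) -> None:
    """Write the genotype component of a cohort as the TSV dialect read back
    by :func:`read_genotype_table`."""
    amp_ids = sorted(cohort.genotypes)
    patients = sorted({p for a in amp_ids for p in cohort.genotypes[a]})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id"] + amp_ids)
        for pid in patients:
            row = [pid]
            for aid in amp_ids:
                g = cohort.genotypes[aid].get(pid)
                row.append(missing_token if g is None else f"{g[0]}/{g[1]}")
            writer.writerow(row)


_CLINICAL_COLS = ("patient_id", "visit", "tjc28", "sjc28", "patient_global",
                  "crp", "das28", "drug")


def read_clinical_table(path, missing_token: str = MISSING_TOKEN
                        ) -> list[ClinicalRecord]:
    """Read a clinical TSV/CSV (delimiter sniffed from the header line)."""
    with open(path, newline="") as fh:
        sample = fh.readline()
        delim = "\t" if "\t" in sample else ","
        fh.seek(0)
        records = []
        for row in csv.DictReader(fh, delimiter=delim):
            def get(col, cast):
                v = row.get(col)
                if v is None or v.strip() == "" or v.strip() == missing_token:
                    return None
                return cast(v)

            records.append(
                ClinicalRecord(
                    patient_id=row["patient_id"].strip(),
                    visit=row["visit"].strip(),
                    tjc28=get("tjc28", lambda v: int(float(v))),
                    sjc28=get("sjc28", lambda v: int(float(v))),
                    patient_global=get("patient_global", float),
                    crp=get("crp", float),
                    das28=get("das28", float),
                    drug=get("drug", str.strip),
                )
            )
    return records


def write_clinical_table(path, records: Iterable[ClinicalRecord],
                         missing_token: str = MISSING_TOKEN) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CLINICAL_COLS)
        for r in records:
            writer.writerow([
                r.patient_id, r.visit,
                *(missing_token if v is None else v
                  for v in (r.tjc28, r.sjc28, r.patient_global, r.crp)),
                missing_token if r.das28 is None else f"{r.das28:.6g}",
                missing_token if r.drug is None else r.drug,
            ])


def attach_clinical(cohort: Cohort, records: Iterable[ClinicalRecord]) -> Cohort:
    """Index clinical records into the cohort by patient and visit."""
    for r in records:
        visits = cohort.clinical.setdefault(r.patient_id, {})
        if r.visit in visits:
            raise ValueError(f"duplicate visit {r.visit!r} for patient {r.patient_id!r}")
        visits[r.visit] = r
    return cohort


def genotyping_rate(cohort: Cohort, amplicon_id: str) -> GenotypingRate:
    """Fraction of patients with a non-missing call at ``amplicon_id``.

    Computed over every patient with a row at this amplicon (patients absent
    from the clinical table still count: QC is cohort-wide).
    """
    if amplicon_id not in cohort.genotypes:
        raise KeyError(f"unknown amplicon {amplicon_id!r}")
    table = cohort.genotypes[amplicon_id]
    if not table:
        raise ValueError(f"no patients for amplicon {amplicon_id!r}")
    n_called = sum(1 for g in table.values() if g is not None)
    return GenotypingRate(amplicon_id, n_called, len(table))
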