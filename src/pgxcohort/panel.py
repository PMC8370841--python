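"""Pharmacogene test panel definition and genotype ingestion.

The packaged panel covers 54 genes and 104 unique rsID-named variant
sites (one rsID, rs2952768, is annotated under three gene contexts)
plus the 5-HTTLPR length polymorphism in *SLC6A4*, carried as the
pseudo-site ``SLC6A4_5HTTLPR`` because it has no rsID. Each site carries a gene
symbol, a scoring category and a fixed reference/alternate allele
annotation so that zygosity is decidable from allele strings.

Genotype data enter either as a long-format table
(``patient_id,rsid,genotype``) or as a multi-sample VCF keyed on the ID
column.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

PANEL_VERSION = "1.0"

#: Site categories used by the scoring rules.
CATEGORIES = ("pk_enzyme", "receptor", "transporter", "other_pd", "non_scored")

#: Categories whose variants count toward the pharmacodynamic tally.
PD_CATEGORIES = frozenset({"receptor", "transporter", "other_pd"})


class GenotypeClass(str, Enum):
    """Diploid genotype state at one panel site."""

    REF_HOMOZYGOUS = "ref_homozygous"
    HETEROZYGOUS = "heterozygous"
    VARIANT_HOMOZYGOUS = "variant_homozygous"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class PanelEntry:
    """One gene-context row of the test panel."""

    gene: str
    rsid: str
    category: str
    ref: str
    alt: str
    star_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.rsid}")


@dataclass(frozen=True)
class PanelDefinition:
    """The full test panel: gene-context entries plus lookup helpers."""

    entries: tuple[PanelEntry, ...]
    version: str = PANEL_VERSION

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.gene, e.rsid)
            if key in seen:
                raise ValueError(f"duplicate panel entry {key}")
            seen.add(key)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({e.gene for e in self.entries}))

    @property
    def rsids(self) -> frozenset[str]:
        """Unique site identifiers (rs2952768 counted once)."""
        return frozenset(e.rsid for e in self.entries)

    def entries_for_gene(self, gene: str) -> tuple[PanelEntry, ...]:
        return tuple(e for e in self.entries if e.gene == gene)

    def sites_for_gene(self, gene: str) -> tuple[str, ...]:
        return tuple(e.rsid for e in self.entries_for_gene(gene))

    def reference_allele(self, rsid: str) -> str:
        for e in self.entries:
            if e.rsid == rsid:
                return e.ref
        raise KeyError(rsid)

    def categories_of(self, rsid: str) -> frozenset[str]:
        """All categories a site appears under (rs2952768 spans three)."""
        cats = frozenset(e.category for e in self.entries if e.rsid == rsid)
        if not cats:
            raise KeyError(rsid)
        return cats

    def is_pd_site(self, rsid: str) -> bool:
        """A site counts toward the PD tally if any of its gene contexts
        is a receptor/transporter/other-PD category."""
        return bool(self.categories_of(rsid) & PD_CATEGORIES)


@dataclass(frozen=True)
class GenotypeCall:
    rsid: str
    genotype_class: GenotypeClass
    raw_alleles: Optional[str] = None


@dataclass
class PatientGenotype:
    """All calls for one patient, keyed by rsID.

    ``cyp2d6_copy_number`` defaults to 2 diploid copies; the SNP panel
    itself cannot see gene duplications, so ultrarapid CYP2D6 calls
    require this field to be set explicitly.
    """

    patient_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    cyp2d6_copy_number: int = 2

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.cyp2d6_copy_number < 0:
            raise ValueError("cyp2d6_copy_number must be >= 0")

    def genotype_class(self, rsid: str) -> GenotypeClass:
        call = self.calls.get(rsid)
        return call.genotype_class if call is not None else GenotypeClass.NO_CALL


class InputFormatError(ValueError):
    """Malformed or inconsistent input data."""


class EmptyInputError(InputFormatError):
    """Input file contains no records."""


def load_default_panel() -> PanelDefinition:
    """Load the packaged 54-gene / 104-site panel."""
    text = resources.files("pgxcohort.data").joinpath("panel_sites.tsv").read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    entries = []
    for row in reader:
        entries.append(
            PanelEntry(
                gene=row["gene"],
                rsid=row["rsid"],
                category=row["category"],
                ref=row["ref"],
                alt=row["alt"],
                star_allele=row.get("star_allele") or None,
            )
        )
    return PanelDefinition(entries=tuple(entries))


def classify_alleles(alleles: str, ref: str) -> GenotypeClass:
    """Map a slash-separated allele pair to a genotype class against a
    fixed reference allele. Unknown strings map to ``no_call``."""
    alleles = alleles.strip()
    if alleles in ("./.", ".", "", "./"):
        return GenotypeClass.NO_CALL
    parts = alleles.split("/")
    if len(parts) != 2 or any(not p or p == "." for p in parts):
        return GenotypeClass.NO_CALL
    n_ref = sum(1 for p in parts if p.upper() == ref.upper())
    if n_ref == 2:
        return GenotypeClass.REF_HOMOZYGOUS
    if n_ref == 1:
        return GenotypeClass.HETEROZYGOUS
    return GenotypeClass.VARIANT_HOMOZYGOUS


REQUIRED_TABLE_COLUMNS = ("patient_id", "rsid", "genotype")


def parse_genotype_table(
    path: Union[str, Path], panel: Optional[PanelDefinition] = None
) -> list[PatientGenotype]:
    """Read a long-format genotype table into per-patient genotypes.

    The optional column ``cyp2d6_copy_number`` (one value per patient,
    repeated or given on any of the patient's rows) feeds the CYP2D6
    duplication input. Genotype strings that match neither allele of the
    panel annotation are kept verbatim as ``variant_homozygous`` only
    when both alleles agree with the alt; anything unparseable becomes
    ``no_call`` with a warning.
    """
    panel = panel or load_default_panel()
    path = Path(path)
    with open(path, newline="") as fh:
        sniff = fh.read(4096)
        fh.seek(0)
        first_line = sniff.splitlines()[0] if sniff else ""
        delimiter = "\t" if "\t" in first_line else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty genotype table")
        missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise InputFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        rows = list(reader)
    if not rows:
        raise EmptyInputError(f"{path}: no genotype rows")

    patients: dict[str, PatientGenotype] = {}
    conflicts: list[str] = []
    n_unknown = 0
    for row in rows:
        pid = row["patient_id"].strip()
        rsid = row["rsid"].strip()
        raw = row["genotype"].strip()
        if not pid:
            raise InputFormatError(f"{path}: row with empty patient_id")
        pg = patients.setdefault(pid, PatientGenotype(patient_id=pid))
        cn = (row.get("cyp2d6_copy_number") or "").strip()
        if cn:
            pg.cyp2d6_copy_number = int(cn)
        try:
            ref = panel.reference_allele(rsid)
            cls = classify_alleles(raw, ref)
        except KeyError:
            cls = GenotypeClass.NO_CALL
        if cls is GenotypeClass.NO_CALL and raw not in ("./.", ".", ""):
            n_unknown += 1
            logger.warning("unparseable genotype %r at %s for %s -> no_call", raw, rsid, pid)
        call = GenotypeCall(rsid=rsid, genotype_class=cls, raw_alleles=raw or None)
        prev = pg.calls.get(rsid)
        if prev is not None and prev.raw_alleles != call.raw_alleles:
            conflicts.append(f"{pid}/{rsid}: {prev.raw_alleles!r} vs {call.raw_alleles!r}")
        pg.calls[rsid] = call
    if conflicts:
        raise InputFormatError(
            f"{path}: conflicting duplicate genotype rows: " + "; ".join(conflicts)
        )
    if n_unknown:
        logger.warning("%d unknown genotype strings coerced to no_call", n_unknown)
    return list(patients.values())


def write_genotype_table(
    genotypes: Iterable[PatientGenotype], path: Union[str, Path]
) -> None:
    """Write patient genotypes back to the long tabular format
    (round-trips with :func:`parse_genotype_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_TABLE_COLUMNS) + ["cyp2d6_copy_number"])
        for pg in genotypes:
            for rsid in sorted(pg.calls):
                call = pg.calls[rsid]
                writer.writerow(
                    [pg.patient_id, rsid, call.raw_alleles or "./.", pg.cyp2d6_copy_number]
                )


def _gt_to_class(gt_alleles: Sequence[Optional[int]]) -> GenotypeClass:
    if any(a is None for a in gt_alleles) or len(gt_alleles) != 2:
        return GenotypeClass.NO_CALL
    n_alt = sum(1 for a in gt_alleles if a != 0)
    if n_alt == 0:
        return GenotypeClass.REF_HOMOZYGOUS
    if n_alt == 1:
        return GenotypeClass.HETEROZYGOUS
    return GenotypeClass.VARIANT_HOMOZYGOUS


def parse_vcf(
    path: Union[str, Path], panel: Optional[PanelDefinition] = None
) -> list[PatientGenotype]:
    """Read a multi-sample VCF, matching sites to the panel by rsID.

    Non-panel sites are ignored (with a logged count). VCF genotype
    indices are interpreted directly: 0/0 reference-homozygous, 0/x
    heterozygous, x/y (x,y > 0) variant-homozygous, missing -> no_call.
    """
    import pysam

    panel = panel or load_default_panel()
    path = Path(path)
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise InputFormatError(f"{path}: VCF has no sample columns")
    patients = {s: PatientGenotype(patient_id=s) for s in samples}
    panel_rsids = panel.rsids
    n_skipped = 0
    for rec in vcf:
        rsid = rec.id
        if rsid is None or rsid not in panel_rsids:
            n_skipped += 1
            continue
        for s in samples:
            gt = rec.samples[s].get("GT")
            cls = _gt_to_class(gt) if gt is not None else GenotypeClass.NO_CALL
            raw = None
            if gt is not None and all(a is not None for a in gt):
                alleles = rec.alleles
                raw = "/".join(alleles[a] for a in gt)
            patients[s].calls[rsid] = GenotypeCall(rsid, cls, raw)
    if n_skipped:
        logger.info("ignored %d non-panel VCF sites", n_skipped)
    for s, pg in patients.items():
        if not pg.calls:
            logger.warning("sample %s: no panel sites found in VCF", s)
    return [patients[s] for s in samples]


@dataclass
class PatientValidation:
    patient_id: str
    missing_sites: tuple[str, ...]
    no_call_fraction: float
    unknown_rsids: tuple[str, ...]
    uncallable_genes: tuple[str, ...]
    flagged: bool


@dataclass
class ValidationReport:
    patients: list[PatientValidation]
    missingness_threshold: float

    @property
    def flagged_patients(self) -> list[str]:
        return [p.patient_id for p in self.patients if p.flagged]


def validate_cohort(
    genotypes: Sequence[PatientGenotype],
    panel: Optional[PanelDefinition] = None,
    missingness_threshold: float = 0.2,
) -> ValidationReport:
    """Report per-patient panel coverage. Patients over the missingness
    threshold are flagged, never dropped."""
    panel = panel or load_default_panel()
    panel_rsids = panel.rsids
    n_sites = len(panel_rsids)
    report = []
    for pg in genotypes:
        missing = tuple(sorted(panel_rsids - set(pg.calls)))
        unknown = tuple(sorted(set(pg.calls) - panel_rsids))
        n_no_call = sum(
            1
            for r in panel_rsids
            if pg.genotype_class(r) is GenotypeClass.NO_CALL
        )
        frac = n_no_call / n_sites
        uncallable = tuple(
            g
            for g in ("CYP2D6", "CYP2C19")
            if all(
                pg.genotype_class(r) is GenotypeClass.NO_CALL
                for r in panel.sites_for_gene(g)
            )
        )
        report.append(
            PatientValidation(
                patient_id=pg.patient_id,
                missing_sites=missing,
                no_call_fraction=frac,
                unknown_rsids=unknown,
                uncallable_genes=uncallable,
                flagged=frac > missingness_threshold,
            )
        )
        for g in uncallable:
            logger.warning("patient %s: %s uncallable (all sites no_call)", pg.patient_id, g)
    return ValidationReport(patients=report, missingness_threshold=missingness_threshold)
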