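"""Wheat gene-identifier parsing and the homoeolog triad registry.

Hexaploid bread wheat (*Triticum aestivum*, AABBDD) carries three ancestral
subgenomes; most nuclear genes exist as a homoeolog triad with one copy per
subgenome, and some (e.g. the RbcS family) as tandem multi-copy groups. RefSeq
locus identifiers such as ``TraesCS7A02G341000`` encode species (``Traes``),
accession (``CS``, Chinese Spring), chromosome + subgenome (``7A``), assembly
version (``02``) and a numeric locus identifier; transcript isoforms carry a
decimal suffix (``.1``, ``.2``). Loci mapped to the unassigned-chromosome bin
are written with ``U`` in place of the chromosome/subgenome pair and carry no
subgenome information of their own — they enter an analysis only through an
explicit, recorded subgenome override.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "UNASSIGNED",
    "SUBGENOMES",
    "GeneLocus",
    "RegistryEntry",
    "TriadRegistry",
    "GeneIdError",
    "RegistryError",
    "RegistryWarning",
    "parse_gene_id",
    "load_registry",
    "packaged_registry_path",
    "count_loci",
    "group_by_gene",
]

UNASSIGNED = "unassigned"
SUBGENOMES = ("A", "B", "D")


class GeneIdError(ValueError):
    """A gene/transcript identifier does not follow the locus nomenclature."""


class RegistryError(ValueError):
    """The triad-registry table is structurally invalid."""


class RegistryWarning(UserWarning):
    """Non-fatal registry issue (e.g. a gene missing a subgenome copy)."""


_SPECIES_RE = re.compile(r"^[A-Z][a-z]+")
_BODY_RE = re.compile(
    r"^(?P<acc>[A-Z]{2})"
    r"(?P<chrsg>U|[1-7][ABD])"
    r"(?P<ver>\d{2})"
    r"G(?P<locus>\d+)"
    r"(?:\.(?P<iso>\d+))?$"
)


@dataclass(frozen=True)
class GeneLocus:
    """One parsed Gene_ID / Transcript_ID.

    ``locus_number`` is kept as a string so that leading zeros survive a
    parse/serialize round trip. ``isoform`` is present exactly when the raw
    identifier carried a decimal transcript suffix.
    """

    raw_id: str
    species_code: str
    accession_code: str
    chromosome: int | str  # 1..7 or UNASSIGNED
    subgenome: str  # "A" | "B" | "D" | "unknown"
    assembly_version: str
    locus_number: str
    isoform: int | None = None

    def to_id(self) -> str:
        """Re-serialize the parsed fields into the identifier string."""
        chrsg = "U" if self.chromosome == UNASSIGNED else f"{self.chromosome}{self.subgenome}"
        suffix = "" if self.isoform is None else f".{self.isoform}"
        return (
            f"{self.species_code}{self.accession_code}{chrsg}"
            f"{self.assembly_version}G{self.locus_number}{suffix}"
        )


def parse_gene_id(raw_id: str) -> GeneLocus:
    """Parse a wheat Gene_ID or Transcript_ID into its structured fields.

    Raises :class:`GeneIdError` naming the offending segment for malformed
    identifiers. Chromosome-``U`` identifiers yield
    ``chromosome="unassigned"`` and ``subgenome="unknown"``.
    """
    if not isinstance(raw_id, str) or not raw_id:
        raise GeneIdError("empty identifier")
    m = _SPECIES_RE.match(raw_id)
    if m is None:
        raise GeneIdError(
            f"{raw_id!r}: species segment must be a capitalised letter prefix (e.g. 'Traes')"
        )
    species = m.group(0)
    body = raw_id[len(species):]
    bm = _BODY_RE.match(body)
    if bm is None:
        # Staged checks purely for the error message.
        if not re.match(r"^[A-Z]{2}", body):
            raise GeneIdError(f"{raw_id!r}: missing two-letter accession segment after {species!r}")
        rest = body[2:]
        if not re.match(r"^(U|[1-7][ABD])", rest):
            raise GeneIdError(
                f"{raw_id!r}: chromosome/subgenome segment must be 'U' or 1-7 followed by A/B/D"
            )
        rest2 = re.sub(r"^(U|[1-7][ABD])", "", rest)
        if not re.match(r"^\d{2}", rest2):
            raise GeneIdError(f"{raw_id!r}: missing two-digit assembly-version segment")
        if not rest2[2:].startswith("G"):
            raise GeneIdError(f"{raw_id!r}: missing 'G' locus segment")
        raise GeneIdError(f"{raw_id!r}: locus number must be numeric with optional decimal isoform")
    chrsg = bm.group("chrsg")
    if chrsg == "U":
        chromosome: int | str = UNASSIGNED
        subgenome = "unknown"
    else:
        chromosome = int(chrsg[0])
        subgenome = chrsg[1]
    iso = bm.group("iso")
    if iso is not None and int(iso) <= 0:
        raise GeneIdError(f"{raw_id!r}: isoform suffix must be a positive integer")
    return GeneLocus(
        raw_id=raw_id,
        species_code=species,
        accession_code=bm.group("acc"),
        chromosome=chromosome,
        subgenome=subgenome,
        assembly_version=bm.group("ver"),
        locus_number=bm.group("locus"),
        isoform=None if iso is None else int(iso),
    )


@dataclass(frozen=True)
class RegistryEntry:
    gene_name: str
    locus: GeneLocus
    effective_subgenome: str  # "A" | "B" | "D"
    override_flag: bool
    override_note: str | None = None


@dataclass
class TriadRegistry:
    """Gene → subgenome → loci mapping with recorded manual overrides."""

    entries: list[RegistryEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.gene_name, None)
        return list(seen)

    def loci_for(self, gene_name: str, subgenome: str | None = None) -> list[GeneLocus]:
        if gene_name not in set(e.gene_name for e in self.entries):
            raise KeyError(f"unknown gene name: {gene_name!r}")
        return [
            e.locus
            for e in self.entries
            if e.gene_name == gene_name
            and (subgenome is None or e.effective_subgenome == subgenome)
        ]

    def overrides(self) -> list[RegistryEntry]:
        return [e for e in self.entries if e.override_flag]


def packaged_registry_path():
    """Path to the packaged wheat Rubiscosome registry (70 loci, 11 genes)."""
    return resources.files("triadbalance").joinpath("data/rubiscosome_registry.tsv")


def _read_table(table_source) -> pd.DataFrame:
    if isinstance(table_source, pd.DataFrame):
        return table_source.copy()
    try:
        df = pd.read_csv(table_source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_name", "gene_id"])
    return df


def load_registry(
    table_source,
    overrides: Mapping[str, str] | None = None,
) -> TriadRegistry:
    """Load and validate a triad-registry table.

    ``table_source`` is a TSV path / file-like / DataFrame with columns
    ``gene_name`` and ``gene_id`` and an optional ``subgenome_override``
    column. ``overrides`` maps raw identifiers (which must be present in the
    table) to an effective subgenome; it takes precedence over the table
    column. Every unassigned-chromosome locus must be covered by an override —
    guessing a subgenome silently is not permitted. A gene missing a copy in
    some subgenome loads with a :class:`RegistryWarning`, not an error.
    """
    df = _read_table(table_source)
    required = {"gene_name", "gene_id"}
    if not required.issubset(df.columns):
        raise RegistryError(f"registry table must have columns {sorted(required)}")
    overrides = dict(overrides or {})

    ids = list(df["gene_id"])
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise RegistryError(f"duplicate gene_id in registry table: {dup}")
    missing = sorted(set(overrides) - set(ids))
    if missing:
        raise RegistryError(f"overrides reference IDs absent from the table: {missing}")

    entries: list[RegistryEntry] = []
    unresolved: list[str] = []
    for row in df.itertuples(index=False):
        locus = parse_gene_id(row.gene_id)
        table_ov = getattr(row, "subgenome_override", "") or ""
        ov = overrides.get(row.gene_id, table_ov.strip() or None)
        if ov is not None and ov not in SUBGENOMES:
            raise RegistryError(f"{row.gene_id}: override subgenome must be one of {SUBGENOMES}, got {ov!r}")
        if ov is not None:
            eff = ov
            flag = eff != locus.subgenome
            note = f"manual assignment to subgenome {ov}" if flag else None
        elif locus.subgenome in SUBGENOMES:
            eff, flag, note = locus.subgenome, False, None
        else:
            unresolved.append(row.gene_id)
            continue
        entries.append(RegistryEntry(row.gene_name, locus, eff, flag, note))
    if unresolved:
        raise RegistryError(
            "loci on an unassigned chromosome need an explicit subgenome override: "
            + ", ".join(unresolved)
        )

    reg = TriadRegistry(entries)
    for gene in reg.gene_names():
        present = {e.effective_subgenome for e in entries if e.gene_name == gene}
        lacking = [s for s in SUBGENOMES if s not in present]
        if lacking:
            warnings.warn(
                f"gene {gene!r} has no locus in subgenome(s) {lacking}; triad is incomplete",
                RegistryWarning,
                stacklevel=2,
            )
    return reg


def load_packaged_registry() -> TriadRegistry:
    """Load the packaged wheat Rubiscosome registry fixture."""
    with resources.as_file(packaged_registry_path()) as p:
        return load_registry(p)


def count_loci(
    registry: TriadRegistry,
    gene_name: str | None = None,
    subgenome: str | None = None,
) -> int:
    """Count registry entries matching the optional gene/subgenome filters."""
    if gene_name is not None and gene_name not in set(e.gene_name for e in registry.entries):
        raise KeyError(f"unknown gene name: {gene_name!r}")
    if subgenome is not None and subgenome not in SUBGENOMES:
        raise ValueError(f"subgenome must be one of {SUBGENOMES}")
    return sum(
        1
        for e in registry.entries
        if (gene_name is None or e.gene_name == gene_name)
        and (subgenome is None or e.effective_subgenome == subgenome)
    )


def group_by_gene(registry: TriadRegistry) -> dict[str, dict[str, list[GeneLocus]]]:
    """Partition registry loci as gene → {A: [...], B: [...], D: [...]}."""
    out: dict[str, dict[str, list[GeneLocus]]] = {}
    for e in registry.entries:
        groups = out.setdefault(e.gene_name, {s: [] for s in SUBGENOMES})
        groups[e.effective_subgenome].append(e.locus)
    return out
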