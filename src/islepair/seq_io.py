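"""Codon-alignment and manifest input/output.

All downstream statistics operate on :class:`CodonAlignment` objects: in-frame
DNA alignments with a shared codon-level mask.  Any codon column containing a
gap or ``N`` in *any* sequence is masked for *all* sequences (complete deletion
at codon granularity), so site denominators are identical across sequences.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "ComparisonManifest",
    "AlignmentError",
    "FrameError",
    "ManifestError",
    "GENETIC_CODES",
    "GENOMES",
    "TAXON_GROUPS",
    "DIRECTIONS",
    "genetic_code_table",
    "read_codon_alignment",
    "write_codon_alignment",
    "build_alignment",
    "read_manifest",
    "write_manifest",
    "concatenate_loci",
]

#: Supported genetic codes -> NCBI translation table ids.
GENETIC_CODES = {
    "standard": 1,
    "vertebrate-mitochondrial": 2,
    "invertebrate-mitochondrial": 5,
    "plant-plastid": 11,
}

GENOMES = ("mitochondrial", "nuclear", "chloroplast")
TAXON_GROUPS = ("bird", "invertebrate", "reptile", "mammal", "amphibian", "plant")
DIRECTIONS = ("mainland_to_island", "island_to_mainland")

_VALID_RESIDUES = frozenset("ACGTN-")
_BASES = "ACGT"


class AlignmentError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class FrameError(AlignmentError):
    """Raised when an alignment violates codon frame or genetic-code rules."""


class ManifestError(ValueError):
    """Raised for malformed comparison manifests."""


class _CodeTables:
    """Cached lookups for one NCBI genetic code."""

    def __init__(self, name: str):
        if name not in GENETIC_CODES:
            raise ValueError(
                f"unknown genetic code {name!r}; expected one of {sorted(GENETIC_CODES)}"
            )
        table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[name]]
        self.name = name
        self.stop_codons = frozenset(table.stop_codons)
        self.forward = dict(table.forward_table)
        self.sense_codons = tuple(
            sorted(
                a + b + c
                for a in _BASES
                for b in _BASES
                for c in _BASES
                if a + b + c not in self.stop_codons
            )
        )

    def translate(self, codon: str) -> str:
        """Amino acid for a sense codon; ``*`` for a stop codon."""
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


_CODE_CACHE: dict[str, _CodeTables] = {}


def genetic_code_table(name: str) -> _CodeTables:
    """Return cached codon/stop lookup tables for a named genetic code."""
    if name not in _CODE_CACHE:
        _CODE_CACHE[name] = _CodeTables(name)
    return _CODE_CACHE[name]


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon alignment with a shared codon-level mask.

    Parameters
    ----------
    sequences:
        ``(sequence_id, residues)`` pairs; residues over ``{A,C,G,T,N,-}``,
        all of identical length divisible by three.
    genome:
        One of :data:`GENOMES`.
    genetic_code:
        One of :data:`GENETIC_CODES`.
    masked:
        Codon indices (0-based) excluded from all computations because some
        sequence has a gap or ``N`` in that codon.
    """

    sequences: tuple[tuple[str, str], ...]
    genome: str = "nuclear"
    genetic_code: str = "standard"
    masked: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.sequences)

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    @property
    def unmasked_codons(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_codons) if i not in self.masked)

    def codon(self, seq_index: int, codon_index: int) -> str:
        return self.sequences[seq_index][1][3 * codon_index : 3 * codon_index + 3]

    def sequence(self, seq_id: str) -> str:
        for sid, residues in self.sequences:
            if sid == seq_id:
                return residues
        raise KeyError(seq_id)

    def subset(self, ids: list[str]) -> "CodonAlignment":
        """Restrict to the given sequence ids, preserving the mask."""
        kept = tuple((sid, self.sequence(sid)) for sid in ids)
        return replace(self, sequences=kept)


def _compute_mask(rows: list[str], n_codons: int) -> frozenset[int]:
    masked = set()
    for i in range(n_codons):
        lo, hi = 3 * i, 3 * i + 3
        for residues in rows:
            triple = residues[lo:hi]
            if "-" in triple or "N" in triple:
                masked.add(i)
                break
    return frozenset(masked)


def build_alignment(
    sequences,
    genome: str = "nuclear",
    genetic_code: str = "standard",
    trim_terminal_stop: bool = True,
) -> CodonAlignment:
    """Validate raw ``(id, residues)`` pairs into a :class:`CodonAlignment`.

    Enforces the frame invariants: equal lengths divisible by three, residues
    restricted to ``{A,C,G,T,N,-}``, and no internal stop codons in unmasked
    columns under the declared genetic code.  A trailing stop codon present in
    any sequence is trimmed from all sequences.
    """
    sequences = [(str(sid), str(res).upper()) for sid, res in sequences]
    if not sequences:
        raise AlignmentError("alignment contains no sequences")
    if genome not in GENOMES:
        raise ValueError(f"unknown genome {genome!r}; expected one of {GENOMES}")
    code = genetic_code_table(genetic_code)

    lengths = {len(res) for _, res in sequences}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3 != 0:
        raise FrameError(f"alignment length {length} is not a multiple of 3")
    for sid, res in sequences:
        bad = set(res) - _VALID_RESIDUES
        if bad:
            raise AlignmentError(f"sequence {sid!r} contains invalid residues {sorted(bad)}")

    n_codons = length // 3
    rows = [res for _, res in sequences]
    masked = _compute_mask(rows, n_codons)

    if trim_terminal_stop and n_codons > 0:
        last = n_codons - 1
        if last not in masked and any(
            code.is_stop(res[3 * last : 3 * last + 3]) for res in rows
        ):
            sequences = [(sid, res[: 3 * last]) for sid, res in sequences]
            rows = [res for _, res in sequences]
            n_codons = last
            masked = frozenset(i for i in masked if i < n_codons)

    for sid, res in sequences:
        for i in range(n_codons):
            if i in masked:
                continue
            if code.is_stop(res[3 * i : 3 * i + 3]):
                raise FrameError(
                    f"internal stop codon in sequence {sid!r} at codon {i + 1} "
                    f"under genetic code {genetic_code!r}"
                )

    return CodonAlignment(
        sequences=tuple(sequences),
        genome=genome,
        genetic_code=genetic_code,
        masked=masked,
    )


def read_codon_alignment(
    path,
    genetic_code: str = "standard",
    genome: str = "nuclear",
) -> CodonAlignment:
    """Read a FASTA codon alignment and validate its frame.

    Terminal stop codons are trimmed; the codon mask is populated from gaps
    and ``N`` residues.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return build_alignment(
        [(rec.id, str(rec.seq)) for rec in records],
        genome=genome,
        genetic_code=genetic_code,
    )


def write_codon_alignment(alignment: CodonAlignment, path) -> None:
    """Write the alignment as wrapped multi-FASTA."""
    records = [
        SeqRecord(Seq(res), id=sid, description="") for sid, res in alignment.sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate_loci(alignments: list[CodonAlignment]) -> CodonAlignment:
    """Codon-wise concatenation of loci sharing a species set and genome.

    Per-locus masking is preserved (mask indices are shifted by the cumulative
    codon offset).  Sequence order follows the first alignment.
    """
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    first = alignments[0]
    if len(alignments) == 1:
        return first
    genomes = {aln.genome for aln in alignments}
    if len(genomes) > 1:
        raise AlignmentError(f"cannot concatenate across genomes {sorted(genomes)}")
    codes = {aln.genetic_code for aln in alignments}
    if len(codes) > 1:
        raise AlignmentError(f"cannot concatenate across genetic codes {sorted(codes)}")
    species = set(first.ids)
    for aln in alignments[1:]:
        if set(aln.ids) != species:
            raise AlignmentError(
                f"species sets differ: {sorted(species)} vs {sorted(aln.ids)}"
            )

    parts = {sid: [] for sid in first.ids}
    masked: set[int] = set()
    offset = 0
    for aln in alignments:
        for sid in first.ids:
            parts[sid].append(aln.sequence(sid))
        masked.update(offset + i for i in aln.masked)
        offset += aln.n_codons
    sequences = tuple((sid, "".join(parts[sid])) for sid in first.ids)
    return CodonAlignment(
        sequences=sequences,
        genome=first.genome,
        genetic_code=first.genetic_code,
        masked=frozenset(masked),
    )


@dataclass(frozen=True)
class ComparisonManifest:
    """One island-mainland-outgroup comparison and its input files."""

    comparison_id: str
    island_species: tuple[str, ...]
    mainland_species: tuple[str, ...]
    outgroup_species: str
    genome: str
    taxon_group: str
    direction: str = "mainland_to_island"
    island_range_km2: float | None = None
    mainland_range_km2: float | None = None
    #: species id -> within-species alignment path (polymorphism input)
    polymorphism_files: dict[str, str] = field(default_factory=dict)
    #: single between-species ortholog alignment path (divergence input)
    divergence_file: str | None = None
    genetic_code: str | None = None

    @property
    def range_ratio(self) -> float | None:
        """Island/mainland range-area ratio, when both areas are present."""
        if self.island_range_km2 is None or self.mainland_range_km2 is None:
            return None
        if self.mainland_range_km2 <= 0:
            return None
        return self.island_range_km2 / self.mainland_range_km2

    def default_genetic_code(self) -> str:
        """Manifest override, else an NCBI-convention default per genome/taxon."""
        if self.genetic_code is not None:
            return self.genetic_code
        if self.genome == "mitochondrial":
            if self.taxon_group == "invertebrate":
                return "invertebrate-mitochondrial"
            if self.taxon_group in ("bird", "reptile", "mammal", "amphibian"):
                return "vertebrate-mitochondrial"
            return "standard"
        if self.genome == "chloroplast":
            return "plant-plastid"
        return "standard"


_REQUIRED_COLUMNS = (
    "comparison_id",
    "island_species",
    "mainland_species",
    "outgroup_species",
    "genome",
    "taxon_group",
)
_KNOWN_COLUMNS = _REQUIRED_COLUMNS + (
    "direction",
    "island_range_km2",
    "mainland_range_km2",
    "polymorphism_files",
    "divergence_file",
    "genetic_code",
)
_MISSING_TOKENS = {"", "NA", "na", "none", "None", "."}


def _parse_optional_area(token: str, column: str, cid: str) -> float | None:
    if token in _MISSING_TOKENS:
        return None
    value = float(token)
    if value < 0:
        raise ManifestError(f"{column} for {cid!r} must be nonnegative, got {value}")
    return value


def _parse_species_list(token: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in token.split(",") if s.strip())


def _parse_file_map(token: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if token in _MISSING_TOKENS:
        return out
    for item in token.split(","):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ManifestError(
                f"polymorphism_files entries must be 'species=path', got {item!r}"
            )
        sid, path = item.split("=", 1)
        out[sid.strip()] = path.strip()
    return out


def read_manifest(path) -> list[ComparisonManifest]:
    """Parse the tab-separated comparison manifest.

    Unknown columns are ignored with a logged warning; missing optional
    fields become ``None``, never zero.  Duplicate ``(comparison_id, genome)``
    pairs are an error (the same comparison may appear once per genome and is
    later reduced by the longest-alignment rule).
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ManifestError(f"manifest {path} has no header row")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ManifestError(f"manifest missing required columns: {missing}")
        unknown = [c for c in reader.fieldnames if c not in _KNOWN_COLUMNS]
        if unknown:
            logger.warning("ignoring unknown manifest columns: %s", unknown)
        rows = list(reader)

    entries: list[ComparisonManifest] = []
    seen: set[tuple[str, str]] = set()
    for row in rows:
        cid = (row.get("comparison_id") or "").strip()
        if not cid:
            raise ManifestError("empty comparison_id")
        genome = (row.get("genome") or "").strip()
        if genome not in GENOMES:
            raise ManifestError(f"unknown genome {genome!r} for {cid!r}")
        key = (cid, genome)
        if key in seen:
            raise ManifestError(f"duplicate comparison_id {cid!r} for genome {genome!r}")
        seen.add(key)
        taxon = (row.get("taxon_group") or "").strip()
        if taxon not in TAXON_GROUPS:
            raise ManifestError(f"unknown taxon_group {taxon!r} for {cid!r}")
        direction = (row.get("direction") or "mainland_to_island").strip()
        if direction not in DIRECTIONS:
            raise ManifestError(f"unknown direction {direction!r} for {cid!r}")
        island = _parse_species_list(row.get("island_species") or "")
        mainland = _parse_species_list(row.get("mainland_species") or "")
        if not island or not mainland:
            raise ManifestError(
                f"comparison {cid!r} needs at least one island and one mainland species"
            )
        outgroup = (row.get("outgroup_species") or "").strip()
        if not outgroup:
            raise ManifestError(f"comparison {cid!r} has no outgroup species")
        code = (row.get("genetic_code") or "").strip()
        code = None if code in _MISSING_TOKENS else code
        if code is not None and code not in GENETIC_CODES:
            raise ManifestError(f"unknown genetic_code {code!r} for {cid!r}")
        divergence_file = (row.get("divergence_file") or "").strip()
        divergence_file = "" if divergence_file in _MISSING_TOKENS else divergence_file
        entries.append(
            ComparisonManifest(
                comparison_id=cid,
                island_species=island,
                mainland_species=mainland,
                outgroup_species=outgroup,
                genome=genome,
                taxon_group=taxon,
                direction=direction,
                island_range_km2=_parse_optional_area(
                    (row.get("island_range_km2") or "").strip(), "island_range_km2", cid
                ),
                mainland_range_km2=_parse_optional_area(
                    (row.get("mainland_range_km2") or "").strip(), "mainland_range_km2", cid
                ),
                polymorphism_files=_parse_file_map(
                    (row.get("polymorphism_files") or "").strip()
                ),
                divergence_file=divergence_file or None,
                genetic_code=code,
            )
        )
    return entries


def write_manifest(entries: list[ComparisonManifest], path) -> None:
    """Write entries as a TSV consumable by :func:`read_manifest`."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_KNOWN_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.comparison_id,
                    ",".join(e.island_species),
                    ",".join(e.mainland_species),
                    e.outgroup_species,
                    e.genome,
                    e.taxon_group,
                    e.direction,
                    "NA" if e.island_range_km2 is None else repr(e.island_range_km2),
                    "NA" if e.mainland_range_km2 is None else repr(e.mainland_range_km2),
                    ",".join(f"{s}={p}" for s, p in e.polymorphism_files.items()) or "NA",
                    e.divergence_file or "NA",
                    e.genetic_code or "NA",
                ]
            )
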