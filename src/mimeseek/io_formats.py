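"""Readers and writers for the external formats the pipeline touches.

FASTA proteomes, TSV peptide-count tables, FASTQ amplicon reads and
PDB/mmCIF coordinate files all enter the pipeline through this module.
Amplicon reads are reduced to peptides here as well: the insert between
two fixed flanking sequences is translated with the standard genetic
code and aggregated into per-round counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from mimeseek.structure_metrics import Atom, StructureModel

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Proteome alphabet: the 20 standard residues plus X for unknowns.
PROTEOME_ALPHABET = frozenset(AMINO_ACIDS + "X")

_DNA_ALPHABET = frozenset("ACGT")


@dataclass
class ProteinSet:
    """A set of protein sequences with unique identifiers.

    Sequences are 1-letter amino-acid strings over the 20 standard
    residues plus optional ``X``; k-mers containing ``X`` are discarded
    downstream rather than rejected here.
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ident, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for record {ident!r}")
            if ident in seen:
                raise ValueError(f"duplicate identifier: {ident!r}")
            seen.add(ident)
            bad = set(seq) - PROTEOME_ALPHABET
            if bad:
                raise ValueError(
                    f"record {ident!r} contains non-amino-acid characters: "
                    f"{sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class PeptideCountTable:
    """Per-round peptide read counts from a panning experiment.

    All peptides share a common length L; ``total_reads`` is the sum of
    counts. Stored entries always have count >= 1.
    """

    round_id: str
    entries: dict[str, int]
    total_reads: int = field(default=0)

    def __post_init__(self) -> None:
        lengths = {len(p) for p in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"mixed peptide lengths in table: {sorted(lengths)}")
        for pep, c in self.entries.items():
            if c < 1:
                raise ValueError(f"non-positive count {c} for peptide {pep}")
        total = sum(self.entries.values())
        if self.total_reads == 0:
            self.total_reads = total
        elif self.total_reads != total:
            raise ValueError(
                f"total_reads {self.total_reads} != sum of counts {total}"
            )

    @property
    def peptide_length(self) -> int | None:
        """Common peptide length L, or None for an empty table."""
        for p in self.entries:
            return len(p)
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AmpliconSpec:
    """Fixed flanks and insert size of the peptide-region amplicon."""

    flank5: str
    flank3: str
    insert_codons: int

    def __post_init__(self) -> None:
        for name, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if not flank or set(flank) - _DNA_ALPHABET:
                raise ValueError(f"{name} must be non-empty DNA over ACGT: {flank!r}")
        if self.insert_codons < 1:
            raise ValueError("insert_codons must be >= 1")


def read_fasta(path: str | Path) -> ProteinSet:
    """Read a protein FASTA file into a :class:`ProteinSet`.

    Sequences are uppercased and whitespace-stripped. Characters outside
    the 21-letter alphabet (20 residues + X) raise ``ValueError``, as do
    duplicate identifiers and empty files.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace(" ", "")))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return ProteinSet(records)


def write_fasta(proteins: ProteinSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for ident, seq in proteins:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_peptide_counts(path: str | Path, round_id: str) -> PeptideCountTable:
    """Read a TSV peptide-count table (columns ``peptide``, ``count``).

    ``#``-prefixed lines are ignored; duplicate peptide rows are merged
    by summation. Mixed peptide lengths or invalid counts raise.
    """
    entries: Counter[str] = Counter()
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "peptide" not in header or "count" not in header:
                    raise ValueError(
                        f"{path}: header must contain 'peptide' and 'count' "
                        f"columns, got {header}"
                    )
                ip, ic = header.index("peptide"), header.index("count")
                continue
            pep = fields[ip].strip().upper()
            raw_count = fields[ic].strip()
            try:
                count = int(raw_count)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {raw_count!r}"
                ) from None
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            if count > 0:
                entries[pep] += count
    if header is None:
        raise ValueError(f"{path}: empty peptide count file")
    return PeptideCountTable(round_id=round_id, entries=dict(entries))


def write_peptide_counts(table: PeptideCountTable, path: str | Path) -> None:
    """Write a count table as TSV, counts descending then peptide ascending."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# round_id={table.round_id}\n")
        fh.write("peptide\tcount\n")
        for pep, count in sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{pep}\t{count}\n")


def extract_insert_peptides(
    fastq_path: str | Path, spec: AmpliconSpec, round_id: str = "round"
) -> tuple[PeptideCountTable, dict[str, int]]:
    """Translate amplicon reads into a peptide count table.

    For each read, ``spec.flank5`` and ``spec.flank3`` are located by
    exact substring search (first occurrence); the insert between them
    must be exactly ``3 * insert_codons`` nucleotides and is translated
    with the standard genetic code. Reads failing any step are tallied
    by reason (``missing_flank5``, ``missing_flank3``,
    ``wrong_insert_length``, ``ambiguous_base``, ``stop_codon``) rather
    than raised.

    Returns the aggregated table and the discard tallies.
    """
    tallies: Counter[str] = Counter()
    entries: Counter[str] = Counter()
    expected = 3 * spec.insert_codons
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        read = str(rec.seq).upper()
        i5 = read.find(spec.flank5)
        if i5 < 0:
            tallies["missing_flank5"] += 1
            continue
        start = i5 + len(spec.flank5)
        i3 = read.find(spec.flank3, start)
        if i3 < 0:
            tallies["missing_flank3"] += 1
            continue
        insert = read[start:i3]
        if len(insert) != expected:
            tallies["wrong_insert_length"] += 1
            continue
        if set(insert) - _DNA_ALPHABET:
            tallies["ambiguous_base"] += 1
            continue
        peptide = str(Seq(insert).translate())
        if "*" in peptide:
            tallies["stop_codon"] += 1
            continue
        entries[peptide] += 1
        tallies["kept"] += 1
    table = PeptideCountTable(round_id=round_id, entries=dict(entries))
    return table, dict(tallies)


# ---------------------------------------------------------------------------
# Structure I/O (PDB / mmCIF via gemmi)

def read_structure(
    path: str | Path, include_waters: bool = False
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is read. Alternate locations are resolved per
    atom site: highest occupancy wins, ties broken by altloc identifier
    order. Waters (HOH/WAT/DOD) are excluded unless requested.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure file")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if not include_waters and residue.name in ("HOH", "WAT", "DOD"):
                continue
            # resolve altlocs: group by atom name, keep best occupancy
            by_name: dict[str, list] = {}
            for at in residue:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        res_name=residue.name,
                        atom_name=name,
                        element=best.element.name.upper(),
                        x=best.pos.x,
                        y=best.pos.y,
                        z=best.pos.z,
                        occupancy=best.occ,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no atoms parsed")
    return StructureModel(atoms=atoms)


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB rendering (ATOM records only) of a model."""
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {i % 100000:5d} {name:<4s} {a.res_name:<3s} "
                f"{a.chain[:1]:1s}{a.res_seq:4d}{(a.icode or ' '):1s}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")
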