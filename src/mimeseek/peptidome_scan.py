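"""Self-peptidome mimetic screening.

The proteome is digested into overlapping 10-mers, restricted to
predicted HLA binders (IC50 at most 1 uM by default, with predictions
supplied as an external table), and every surviving peptide is scored
for consistency with the experimentally determined specificity profile.
The top-scoring peptides — potential structural mimetics of the target
epitope — are reported with full protein provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from mimeseek.io_formats import ProteinSet
from mimeseek.panning_profile import SpecificityProfile, score_peptide


@dataclass
class PeptidomeIndex:
    """Deduplicated k-mers with (protein_id, 1-based start) provenance."""

    k: int
    entries: dict[str, list[tuple[str, int]]]
    skipped_x: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def occurrence_count(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass
class AffinityTable:
    """Predicted peptide -> IC50 (nM) map."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for pep, ic50 in self.values.items():
            if not ic50 > 0:
                raise ValueError(f"non-positive IC50 {ic50} for {pep}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MimeticCandidate:
    peptide: str
    score: float
    window_score: float
    ic50_nM: float | None
    provenance: tuple[tuple[str, int], ...]


def kmerize_proteome(proteins: ProteinSet, k: int = 10) -> PeptidomeIndex:
    """All overlapping k-mers of every protein, deduplicated.

    Identical k-mers (e.g. shared between isoforms) are merged with all
    provenance records preserved; k-mers containing X are skipped and
    tallied in ``skipped_x``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    entries: dict[str, list[tuple[str, int]]] = {}
    skipped = 0
    for ident, seq in proteins:
        for start in range(len(seq) - k + 1):
            kmer = seq[start : start + k]
            if "X" in kmer:
                skipped += 1
                continue
            entries.setdefault(kmer, []).append((ident, start + 1))
    return PeptidomeIndex(k=k, entries=entries, skipped_x=skipped)


def load_affinity_table(path: str | Path, dialect: str = "tsv") -> AffinityTable:
    """Load a peptide -> IC50(nM) table.

    ``tsv`` dialect expects columns ``peptide`` and ``ic50_nM``;
    ``netmhcpan`` expects whitespace-delimited prediction rows with
    ``Peptide`` and an affinity-in-nM column (``Aff(nM)`` or
    ``Affinity(nM)``) named in the header. Duplicate peptides keep the
    lowest IC50 (strongest predicted binding).
    """
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", comment="#")
        for col in ("peptide", "ic50_nM"):
            if col not in frame.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        pairs = zip(frame["peptide"].astype(str), frame["ic50_nM"].astype(float))
    elif dialect == "netmhcpan":
        header: list[str] | None = None
        rows: list[tuple[str, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or set(line) == {"-"}:
                    continue
                fields = line.split()
                if header is None and "Peptide" in fields:
                    header = fields
                    continue
                if header is None or not fields[0].lstrip("-").isdigit():
                    continue
                rows.append(tuple(fields))
        if header is None:
            raise ValueError(f"{path}: missing required column 'Peptide'")
        aff_col = next(
            (c for c in ("Aff(nM)", "Affinity(nM)") if c in header), None
        )
        if aff_col is None:
            raise ValueError(f"{path}: missing required column 'Aff(nM)'")
        ip, ia = header.index("Peptide"), header.index(aff_col)
        pairs = ((r[ip], float(r[ia])) for r in rows)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    values: dict[str, float] = {}
    for pep, ic50 in pairs:
        pep = pep.upper()
        if pep not in values or ic50 < values[pep]:
            values[pep] = ic50
    return AffinityTable(values=values)


def filter_binders(
    index: PeptidomeIndex,
    table: AffinityTable,
    threshold_nM: float = 1000.0,
    allow_missing: bool = False,
) -> PeptidomeIndex:
    """Restrict the peptidome to predicted HLA binders.

    Peptides with IC50 <= ``threshold_nM`` (default 1 uM) are retained.
    Peptides absent from the table are excluded by default — the whole
    peptidome is assumed to have gone through the predictor — unless
    ``allow_missing`` passes them through (useful in tests).
    """
    if not threshold_nM > 0:
        raise ValueError("threshold_nM must be > 0")
    entries = {}
    missing = 0
    for pep, prov in index.entries.items():
        ic50 = table.values.get(pep)
        if ic50 is None:
            missing += 1
            if allow_missing:
                entries[pep] = prov
            continue
        if ic50 <= threshold_nM:
            entries[pep] = prov
    out = PeptidomeIndex(k=index.k, entries=entries, skipped_x=index.skipped_x)
    out.missing_from_table = missing  # type: ignore[attr-defined]
    return out


def rank_mimetics(
    index: PeptidomeIndex,
    profile: SpecificityProfile,
    affinity: AffinityTable | None = None,
    mode: str = "full",
    window: tuple[int, int] = (4, 7),
    exclude: set[str] | frozenset[str] = frozenset(),
    top_n: int = 10,
) -> list[MimeticCandidate]:
    """Rank peptidome peptides by specificity-profile consistency.

    ``mode='full'`` ranks by the full-length score, ``'window'`` by the
    central-residue score (default positions 4-7, the TCR binding
    interface of a decamer). Higher scores are more consistent with the
    motif. The target epitope itself belongs in ``exclude``. Each
    candidate carries both score variants, its IC50 when known, and all
    provenance records.
    """
    if mode not in ("full", "window"):
        raise ValueError("mode must be 'full' or 'window'")
    if profile.length != index.k:
        raise ValueError(
            f"profile length {profile.length} != index k {index.k}"
        )
    pool = [p for p in index.entries if p not in exclude]
    if not pool:
        raise ValueError("no peptides to rank after exclusion")
    candidates = []
    for pep in pool:
        full = score_peptide(profile, pep, window=(1, profile.length))
        win = score_peptide(profile, pep, window=window)
        candidates.append(
            MimeticCandidate(
                peptide=pep,
                score=full,
                window_score=win,
                ic50_nM=affinity.values.get(pep) if affinity else None,
                provenance=tuple(index.entries[pep]),
            )
        )
    key = (lambda c: (-c.score, c.peptide)) if mode == "full" else (
        lambda c: (-c.window_score, c.peptide)
    )
    candidates.sort(key=key)
    return candidates[:top_n]


def write_mimetics_tsv(candidates: list[MimeticCandidate], path: str | Path) -> None:
    """Ranked candidate table: peptide, scores, IC50, provenance."""
    with open(path, "w") as fh:
        fh.write("peptide\tscore_full\tscore_window\tic50_nM\tsources\n")
        for c in candidates:
            sources = ";".join(f"{p}:{s}" for p, s in c.provenance)
            ic50 = "" if c.ic50_nM is None or math.isnan(c.ic50_nM) else f"{c.ic50_nM:g}"
            fh.write(
                f"{c.peptide}\t{c.score:.6g}\t{c.window_score:.6g}\t{ic50}\t{sources}\n"
            )
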