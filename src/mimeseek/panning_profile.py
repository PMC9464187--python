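"""Panning-round filtering and the peptide specificity profile.

A panning experiment against a peptide-HLA phage library yields
per-round peptide read counts. The analysis filters out peptides
lacking the canonical HLA C-terminal anchor (position 10 R/K for
HLA-A*11 decamers) and, optionally, singleton isolates, then tallies
the surviving unique peptides into a per-position amino-acid
percent-frequency matrix — the specificity profile. Candidate peptides
are scored against the profile as the product of their per-position
fractional frequencies, optionally restricted to a central window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from mimeseek.io_formats import AMINO_ACIDS, PeptideCountTable

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PeptideSet:
    """Unique peptides of a common length L."""

    peptides: frozenset[str]

    def __post_init__(self) -> None:
        lengths = {len(p) for p in self.peptides}
        if len(lengths) > 1:
            raise ValueError(f"mixed peptide lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(sorted(self.peptides))

    @property
    def peptide_length(self) -> int | None:
        for p in self.peptides:
            return len(p)
        return None


@dataclass
class SpecificityProfile:
    """L x 20 per-position amino-acid percent-frequency matrix.

    ``freq[p, a]`` is the percent frequency of amino acid
    ``AMINO_ACIDS[a]`` at 1-based position ``p + 1``; each position
    (row) sums to 100. ``window`` records an optional 1-based closed
    scoring interval; ``provenance`` records the filter chain that
    produced the underlying peptide set.
    """

    length: int
    freq: np.ndarray  # (L, 20), percent
    pseudocount: float = 0.0
    n_peptides: int = 1
    window: tuple[int, int] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (self.length, 20):
            raise ValueError(
                f"freq shape {self.freq.shape} != ({self.length}, 20)"
            )
        sums = self.freq.sum(axis=1)
        if not np.allclose(sums, 100.0, rtol=1e-9):
            raise ValueError(f"profile positions must sum to 100%, got {sums}")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")

    def frequency(self, position: int, aa: str) -> float:
        """Percent frequency of ``aa`` at 1-based ``position``."""
        return float(self.freq[position - 1, _AA_INDEX[aa]])

    def to_frame(self) -> pd.DataFrame:
        """Rows = 20 amino acids, columns = 1-based positions."""
        return pd.DataFrame(
            self.freq.T,
            index=list(AMINO_ACIDS),
            columns=[str(p) for p in range(1, self.length + 1)],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Serialise as TSV plus a JSON metadata sidecar."""
        self.to_frame().to_csv(path, sep="\t", index_label="aa")
        meta = {
            "length": self.length,
            "pseudocount": self.pseudocount,
            "n_peptides": self.n_peptides,
            "window": list(self.window) if self.window else None,
            "provenance": self.provenance,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpecificityProfile":
        frame = pd.read_csv(path, sep="\t", index_col="aa")
        frame = frame.loc[list(AMINO_ACIDS)]
        meta_path = Path(str(path) + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        window = meta.get("window")
        return cls(
            length=frame.shape[1],
            freq=frame.to_numpy().T,
            pseudocount=meta.get("pseudocount", 0.0),
            n_peptides=meta.get("n_peptides", 1),
            window=tuple(window) if window else None,
            provenance=meta.get("provenance", {}),
        )


def filter_anchor(
    table: PeptideCountTable,
    anchor_position: int | None = None,
    allowed: frozenset[str] | set[str] = frozenset("RK"),
) -> PeptideCountTable:
    """Retain peptides whose anchor residue is in ``allowed``.

    ``anchor_position`` is 1-based and defaults to the C-terminal
    position L (the HLA-A*11 anchor for decamers). Idempotent.
    """
    if not allowed:
        raise ValueError("allowed anchor set must be non-empty")
    length = table.peptide_length
    if anchor_position is None:
        if length is None:
            raise ValueError("cannot infer anchor position from an empty table")
        anchor_position = length
    if length is not None and not (1 <= anchor_position <= length):
        raise ValueError(f"anchor_position {anchor_position} outside [1, {length}]")
    entries = {
        p: c for p, c in table.entries.items() if p[anchor_position - 1] in allowed
    }
    return PeptideCountTable(round_id=table.round_id, entries=entries)


def anchor_read_fraction(
    table: PeptideCountTable,
    anchor_position: int | None = None,
    allowed: frozenset[str] | set[str] = frozenset("RK"),
) -> float:
    """Fraction of reads whose peptide carries an allowed anchor residue."""
    kept = filter_anchor(table, anchor_position, allowed)
    if table.total_reads == 0:
        return 0.0
    return kept.total_reads / table.total_reads


def filter_min_count(table: PeptideCountTable, min_count: int = 2) -> PeptideCountTable:
    """Retain entries with count >= ``min_count`` (default 2, i.e. count > 1)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    entries = {p: c for p, c in table.entries.items() if c >= min_count}
    return PeptideCountTable(round_id=table.round_id, entries=entries)


def unique_peptides(table: PeptideCountTable) -> PeptideSet:
    """The key set of the table, each peptide represented once."""
    return PeptideSet(frozenset(table.entries))


def build_specificity_profile(
    peptides: PeptideSet,
    pseudocount: float = 0.0,
    provenance: dict | None = None,
) -> SpecificityProfile:
    """Tally unique peptides into a percent-frequency profile.

    f_p(aa) = 100 * (count of aa at position p + pseudocount)
                  / (n + 20 * pseudocount)

    With the default pseudocount of 0 the profile reproduces raw percent
    frequencies, so any residue unseen at a position scores zero.
    """
    if len(peptides) == 0:
        raise ValueError("cannot build a profile from an empty peptide set")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    length = peptides.peptide_length
    counts = np.zeros((length, 20))
    for pep in peptides:
        for p, aa in enumerate(pep):
            counts[p, _AA_INDEX[aa]] += 1
    n = len(peptides)
    freq = 100.0 * (counts + pseudocount) / (n + 20.0 * pseudocount)
    return SpecificityProfile(
        length=length,
        freq=freq,
        pseudocount=pseudocount,
        n_peptides=n,
        provenance=provenance or {},
    )


def top_enriched_fraction(
    table: PeptideCountTable, k: int
) -> tuple[list[str], float]:
    """The k most enriched peptides and their share of total reads.

    Ties are broken by count descending then lexicographic peptide. If
    k exceeds the number of entries, all entries are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:k]
    if table.total_reads == 0:
        return [], 0.0
    fraction = sum(c for _, c in top) / table.total_reads
    return [p for p, _ in top], fraction


def score_peptide(
    profile: SpecificityProfile,
    peptide: str,
    window: tuple[int, int] | None = None,
) -> float:
    """Motif-consistency score of a peptide against a profile, in [0, 1].

    The score is the product over scored positions of the fractional
    frequency f_p(aa)/100 — equivalently the raw percent-frequency
    product normalised by the maximum possible product 100^m for m
    scored positions. ``window`` is a 1-based closed interval (e.g.
    (4, 7) for the central TCR-contact residues); omitted, all L
    positions are scored.
    """
    if len(peptide) != profile.length:
        raise ValueError(
            f"peptide length {len(peptide)} != profile length {profile.length}"
        )
    if window is None:
        window = profile.window or (1, profile.length)
    lo, hi = window
    if not (1 <= lo <= hi <= profile.length):
        raise ValueError(f"window {window} outside [1, {profile.length}]")
    score = 1.0
    for p in range(lo, hi + 1):
        score *= profile.frequency(p, peptide[p - 1]) / 100.0
    return score


def plot_profile(profile: SpecificityProfile, path: str | Path) -> None:
    """Render the profile as per-position stacked frequency bars.

    A lightweight logo-style overview: at each position the amino acids
    are stacked by descending frequency and the dominant residues are
    labelled. Intended for quick inspection, not publication logos.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * profile.length, 4.0))
    cmap = plt.get_cmap("tab20")
    for p in range(profile.length):
        order = np.argsort(profile.freq[p])[::-1]
        bottom = 0.0
        for rank, a in enumerate(order):
            f = profile.freq[p, a]
            if f <= 0:
                continue
            ax.bar(p + 1, f, bottom=bottom, color=cmap(a % 20), width=0.8)
            if f >= 10.0:
                ax.text(p + 1, bottom + f / 2, AMINO_ACIDS[a],
                        ha="center", va="center", fontsize=8)
            bottom += f
    ax.set_xlabel("peptide position")
    ax.set_ylabel("frequency (%)")
    ax.set_xticks(range(1, profile.length + 1))
    ax.set_ylim(0, 100)
    ax.set_title(f"specificity profile (n={profile.n_peptides})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def windowed(profile: SpecificityProfile, window: tuple[int, int]) -> SpecificityProfile:
    """A copy of the profile with a default scoring window recorded."""
    lo, hi = window
    if not (1 <= lo <= hi <= profile.length):
        raise ValueError(f"window {window} outside [1, {profile.length}]")
    return replace(profile, window=(lo, hi))
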