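"""Synthetic data generators for every pipeline stage.

These generators emulate the statistical structure of the real inputs
so each analysis stage is testable without downloads: a naive 10-mer
phage library with flat (or NNK-biased) amino-acid composition,
multiplicative per-position selection across panning rounds with a
hidden recognition motif and a C-terminal R/K display bias, proteomes
with planted mimetic 10-mers, K_D(T) series from stated thermodynamic
parameters with multiplicative noise, and toy coordinate models with
analytically known geometry.

Every generator takes an explicit seed and is reproducible bit-for-bit
given the same seed and platform. Ground truth (motif matrices, planted
positions, generator parameters) is always returned alongside or
recorded so tests can assert against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from mimeseek.io_formats import AMINO_ACIDS, AmpliconSpec, PeptideCountTable, ProteinSet
from mimeseek.affinity_thermo import T_REF_DEFAULT, ThermoParams
from mimeseek.structure_metrics import Atom, StructureModel

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class PanningSimConfig:
    """Conditions of a simulated phage-panning experiment.

    The naive library holds ``library_size`` i.i.d. peptides of length
    ``length``. Selection is multiplicative: each peptide's sampling
    weight is its count times the product of per-position motif weights
    ``true_motif[p, aa]`` times an ``anchor_bias`` display factor if the
    C-terminal residue is R or K. Each round resamples ``sample_depth``
    reads multinomially.
    """

    library_size: int = 4_000_000
    length: int = 10
    aa_model: str = "uniform"  # "uniform" | "nnk"
    true_motif: np.ndarray | None = None  # (length, 20) positive weights
    anchor_bias: float = 1.0
    rounds: int = 3
    sample_depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aa_model not in ("uniform", "nnk"):
            raise ValueError("aa_model must be 'uniform' or 'nnk'")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.true_motif is not None:
            self.true_motif = np.asarray(self.true_motif, dtype=float)
            if self.true_motif.shape != (self.length, 20):
                raise ValueError(
                    f"true_motif shape {self.true_motif.shape} != "
                    f"({self.length}, 20)"
                )
            if np.any(self.true_motif <= 0):
                raise ValueError("motif selection weights must be positive")

    def ground_truth(self) -> dict:
        return {
            "library_size": self.library_size,
            "length": self.length,
            "aa_model": self.aa_model,
            "true_motif": None if self.true_motif is None
            else self.true_motif.tolist(),
            "anchor_bias": self.anchor_bias,
            "rounds": self.rounds,
            "sample_depth": self.sample_depth,
            "seed": self.seed,
        }


@dataclass
class ThermoSimConfig:
    """Conditions of a simulated K_D temperature series.

    Defaults mirror an SPR thermodynamics run: measurements at 6 C
    intervals from 6 C to 36 C. Energies in kcal/mol, entropy in
    kcal/(mol K).
    """

    dh: float
    ds: float
    dcp: float = 0.0
    temperatures: tuple[float, ...] = tuple(279.15 + 6.0 * i for i in range(6))
    noise_cv: float = 0.0
    replicates: int = 1
    t_ref: float = T_REF_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def motif_weight_matrix(
    length: int,
    consensus: str,
    positions: tuple[int, int],
    weight: float,
) -> np.ndarray:
    """A flat selection-weight matrix with ``weight`` on the consensus
    residues over a 1-based closed position interval; 1 elsewhere."""
    lo, hi = positions
    if not (1 <= lo <= hi <= length):
        raise ValueError(f"positions {positions} outside [1, {length}]")
    if len(consensus) != hi - lo + 1:
        raise ValueError("consensus length must match the position interval")
    w = np.ones((length, 20))
    for offset, aa in enumerate(consensus):
        w[lo - 1 + offset, _AA_INDEX[aa]] = weight
    return w


def nnk_amino_acid_probabilities() -> np.ndarray:
    """Amino-acid probabilities under NNK codon degeneracy.

    Counts codons N N K (K = G/T) per residue under the standard
    genetic code; stop codons are excluded (resampled), so the
    probabilities are codon counts over the 30 coding NNK codons.
    """
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    counts = np.zeros(20)
    for n1 in "ACGT":
        for n2 in "ACGT":
            for n3 in "GT":
                aa = table.get(n1 + n2 + n3)
                if aa is not None:
                    counts[_AA_INDEX[aa]] += 1
    return counts / counts.sum()


def generate_naive_library(config: PanningSimConfig) -> PeptideCountTable:
    """Draw a naive peptide library of i.i.d. random peptides.

    Under the uniform model every position is uniform over the 20
    standard amino acids (expected frequency 5% each); the nnk model
    weights residues by NNK codon multiplicity.
    """
    if config.library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = np.random.default_rng(config.seed)
    shape = (config.library_size, config.length)
    if config.aa_model == "uniform":
        draws = rng.integers(0, 20, size=shape)
    else:
        draws = rng.choice(20, size=shape, p=nnk_amino_acid_probabilities())
    aa_arr = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    flat = np.ascontiguousarray(aa_arr[draws]).view(f"S{config.length}").ravel()
    uniq, counts = np.unique(flat, return_counts=True)
    entries = {u.decode(): int(c) for u, c in zip(uniq, counts)}
    return PeptideCountTable(round_id="naive", entries=entries)


def simulate_panning(
    library: PeptideCountTable, config: PanningSimConfig
) -> list[PeptideCountTable]:
    """Simulate selection rounds by weighted multinomial resampling.

    Per round, each peptide's weight is count x prod_p w_p(aa_p) x the
    anchor term; the next round draws ``sample_depth`` reads from those
    weights. Models the binding/wash/amplification bottleneck as one
    resampling step. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    length = library.peptide_length or config.length
    peptides = sorted(library.entries)
    counts = np.array([library.entries[p] for p in peptides], dtype=float)

    # per-copy selection weight (motif x anchor), constant across rounds
    ascii_to_idx = np.full(256, -1, dtype=np.int64)
    for aa, i in _AA_INDEX.items():
        ascii_to_idx[ord(aa)] = i
    codes = ascii_to_idx[
        np.frombuffer("".join(peptides).encode(), dtype=np.uint8).reshape(
            len(peptides), length
        )
    ]
    per_copy = np.ones(len(peptides))
    if config.true_motif is not None:
        per_copy *= np.prod(
            config.true_motif[np.arange(length)[None, :], codes], axis=1
        )
    if config.anchor_bias != 1.0:
        anchored = np.isin(codes[:, -1], [_AA_INDEX["R"], _AA_INDEX["K"]])
        per_copy *= np.where(anchored, config.anchor_bias, 1.0)

    rounds: list[PeptideCountTable] = []
    for r in range(1, config.rounds + 1):
        weights = counts * per_copy
        total = weights.sum()
        if total <= 0:
            raise ValueError("all selection weights are zero")
        counts = rng.multinomial(config.sample_depth, weights / total).astype(float)
        nz = np.nonzero(counts)[0]
        entries = {peptides[i]: int(counts[i]) for i in nz}
        rounds.append(PeptideCountTable(round_id=f"round{r}", entries=entries))
    return rounds


def simulate_experiment(config: PanningSimConfig) -> list[PeptideCountTable]:
    """Generate a naive library and run the panning rounds in one pass.

    Statistically equivalent to ``simulate_panning(
    generate_naive_library(config), config)`` but keeps the library as
    integer codes throughout and only decodes peptides that survive a
    round, so multi-million-member libraries stay cheap. The random
    stream differs from the two-step path; results are deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.library_size, config.length)
    if config.aa_model == "uniform":
        codes = rng.integers(0, 20, size=shape)
    else:
        codes = rng.choice(20, size=shape, p=nnk_amino_acid_probabilities())

    per_copy = np.ones(config.library_size)
    if config.true_motif is not None:
        per_copy *= np.prod(
            config.true_motif[np.arange(config.length)[None, :], codes], axis=1
        )
    if config.anchor_bias != 1.0:
        anchored = np.isin(codes[:, -1], [_AA_INDEX["R"], _AA_INDEX["K"]])
        per_copy *= np.where(anchored, config.anchor_bias, 1.0)

    aa_arr = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    counts = np.ones(config.library_size)
    rounds: list[PeptideCountTable] = []
    for r in range(1, config.rounds + 1):
        weights = counts * per_copy
        total = weights.sum()
        if total <= 0:
            raise ValueError("all selection weights are zero")
        counts = rng.multinomial(config.sample_depth, weights / total).astype(float)
        nz = np.nonzero(counts)[0]
        # compact: library members never drawn again cannot reappear
        codes, per_copy, counts = codes[nz], per_copy[nz], counts[nz]
        seqs = np.ascontiguousarray(aa_arr[codes]).view(
            f"S{config.length}"
        ).ravel()
        entries: dict[str, int] = {}
        for s, c in zip(seqs, counts):
            key = s.decode()
            entries[key] = entries.get(key, 0) + int(c)
        rounds.append(PeptideCountTable(round_id=f"round{r}", entries=entries))
    return rounds


# ---------------------------------------------------------------------------
# FASTQ emission

#: Lexicographically first NNK codon per amino acid (deterministic
#: back-translation for read emission).
def _nnk_codon_map() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    mapping: dict[str, str] = {}
    for n1 in "ACGT":
        for n2 in "ACGT":
            for n3 in "GT":
                codon = n1 + n2 + n3
                aa = table.get(codon)
                if aa is not None and (aa not in mapping or codon < mapping[aa]):
                    mapping[aa] = codon
    return mapping


def write_library_fastq(
    table: PeptideCountTable,
    spec: AmpliconSpec,
    path: str | Path,
) -> None:
    """Emit one read per counted peptide occurrence, by deterministic
    NNK back-translation framed by the amplicon flanks."""
    codons = _nnk_codon_map()
    with open(path, "w") as fh:
        i = 0
        for pep in sorted(table.entries):
            insert = "".join(codons[aa] for aa in pep)
            read = spec.flank5 + insert + spec.flank3
            qual = "I" * len(read)
            for _ in range(table.entries[pep]):
                fh.write(f"@read{i}\n{read}\n+\n{qual}\n")
                i += 1


# ---------------------------------------------------------------------------
# Proteome

def generate_synthetic_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    planted: list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> tuple[ProteinSet, list[dict]]:
    """Random proteome with mimetic 10-mers planted at recorded sites.

    ``planted`` lists (peptide, copies). Each copy overwrites a random
    span of a random protein; a position that would corrupt an earlier
    planted span is redrawn (error after 100 attempts). Returns the
    proteome and a ground-truth provenance list of
    ``{"peptide", "protein_id", "start"}`` records (1-based starts).
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid length_range {length_range}")
    planted = planted or []
    for pep, copies in planted:
        if len(pep) > lo:
            raise ValueError(
                f"planted peptide {pep} longer than minimum protein length {lo}"
            )
        if copies < 1:
            raise ValueError("planted copy count must be >= 1")
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    seqs = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))
        for n in lengths
    ]
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth: list[dict] = []
    for pep, copies in planted:
        for _ in range(copies):
            for attempt in range(100):
                pi = int(rng.integers(0, n_proteins))
                max_start = len(seqs[pi]) - len(pep)
                if max_start < 0:
                    continue
                start = int(rng.integers(0, max_start + 1))
                span = (start, start + len(pep))
                clash = any(
                    s < span[1] and span[0] < e
                    for s, e in occupied.get(pi, [])
                )
                if not clash:
                    break
            else:
                raise RuntimeError(
                    f"could not place planted peptide {pep} without collision "
                    "after 100 attempts"
                )
            seqs[pi] = seqs[pi][: span[0]] + pep + seqs[pi][span[1] :]
            occupied.setdefault(pi, []).append(span)
            truth.append(
                {"peptide": pep, "protein_id": f"sp{pi:05d}", "start": start + 1}
            )
    records = [(f"sp{i:05d}", seq) for i, seq in enumerate(seqs)]
    return ProteinSet(records), truth


# ---------------------------------------------------------------------------
# Thermodynamics

def generate_kd_temperature_series(
    config: ThermoSimConfig,
) -> list[tuple[float, float]]:
    """K_D(T) series from stated ΔH/ΔS(/ΔCp) with multiplicative noise.

    K_D(T) = exp(ΔG(T) / (R T)) with the integrated Gibbs-Helmholtz
    ΔG(T); each measurement is multiplied by log-normal noise with
    coefficient of variation ``noise_cv`` (mean 1).
    """
    params = ThermoParams(
        dh=config.dh, ds=config.ds, dcp=config.dcp,
        t_ref=config.t_ref, residual_ss=0.0, model="generator",
    )
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    out: list[tuple[float, float]] = []
    for t in config.temperatures:
        kd0 = params.kd(t)
        for _ in range(config.replicates):
            noise = 1.0
            if sigma > 0:
                noise = math.exp(rng.normal(-0.5 * sigma * sigma, sigma))
            out.append((t, kd0 * noise))
    return out


# ---------------------------------------------------------------------------
# Toy structures

def _atom(chain, res, name, element, pos, res_name="GLY"):
    return Atom(chain, res, "", res_name, name, element,
                float(pos[0]), float(pos[1]), float(pos[2]))


def generate_toy_structure(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic coordinate fixtures with known analytic properties.

    ``two_spheres``: two single-atom chains (roles PEPTIDE / TCRA)
    separated by ``params['distance']`` Angstrom along x; elements from
    ``params.get('elements', ('C', 'C'))``. Analytic SASA/BSA.

    ``helix_pair``: an HLA groove whose helix C-alpha axis runs along
    +x, a peptide chain along +x, and TCR alpha/beta chains whose
    cystine midpoints realise a crossing angle of
    ``params['angle_deg']`` degrees in the groove plane.

    ``displaced_copy``: returns a (mobile, target) model pair where the
    target is a rigidly transformed copy of the mobile with atom 0
    displaced by ``params['shift']`` Angstrom before the transform, so
    the minimum attainable paired RMSD is known.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "two_spheres":
        d = float(params.get("distance", 10.0))
        e1, e2 = params.get("elements", ("C", "C"))
        atoms = [
            _atom("P", 1, "C1", e1, (0.0, 0.0, 0.0)),
            _atom("T", 1, "C1", e2, (d, 0.0, 0.0)),
        ]
        model = StructureModel(atoms=atoms)
        model.assign_roles({"P": "PEPTIDE", "T": "TCRA"})
        return model

    if kind == "helix_pair":
        angle = math.radians(float(params.get("angle_deg", 90.0)))
        atoms = []
        # HLA groove helices parallel to x, flanking the peptide
        for res in range(50, 86):
            atoms.append(_atom("A", res, "CA", "C", ((res - 50) * 1.5, -6.0, 0.0)))
        for res in range(138, 181):
            atoms.append(_atom("A", res, "CA", "C", ((res - 138) * 1.25, 6.0, 0.0)))
        # peptide N->C along +x
        for res in range(1, 11):
            atoms.append(_atom("C", res, "CA", "C", (10.0 + 2.0 * res, 0.0, 4.0)))
        # TCR cystine S-gamma pairs: Vbeta midpoint at origin-side, the
        # Vbeta->Valpha vector at `angle` to +x within the groove plane
        centre = np.array([25.0, 0.0, 30.0])
        direction = np.array([math.cos(angle), math.sin(angle), 0.0])
        vb_mid = centre - 10.0 * direction
        va_mid = centre + 10.0 * direction
        for chain, res_pair, mid in (("D", (23, 104), va_mid), ("E", (23, 104), vb_mid)):
            for res, off in zip(res_pair, (np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]))):
                atoms.append(_atom(chain, res, "SG", "S", mid + off, res_name="CYS"))
        model = StructureModel(atoms=atoms)
        model.assign_roles(
            {"A": "HLA", "C": "PEPTIDE", "D": "TCRA", "E": "TCRB"}
        )
        return model

    if kind == "displaced_copy":
        n = int(params.get("n_atoms", 8))
        shift = float(params.get("shift", 1.0))
        coords = rng.normal(size=(n, 3)) * 5.0
        atoms = [
            _atom("A", i + 1, "CA", "C", coords[i]) for i in range(n)
        ]
        mobile = StructureModel(atoms=list(atoms))
        moved = coords.copy()
        moved[0] += np.array([shift, 0.0, 0.0])
        # arbitrary rigid transform of the displaced copy
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0.0],
             [math.sin(theta), math.cos(theta), 0.0],
             [0.0, 0.0, 1.0]]
        )
        moved = moved @ rot.T + np.array([3.0, -2.0, 7.0])
        target = StructureModel(
            atoms=[_atom("A", i + 1, "CA", "C", moved[i]) for i in range(n)]
        )
        return mobile, target

    raise ValueError(f"unknown toy structure kind {kind!r}")


def write_ground_truth(obj, path: str | Path) -> None:
    """Emit generator ground truth as a JSON sidecar."""
    Path(path).write_text(json.dumps(obj, indent=1, default=str))
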