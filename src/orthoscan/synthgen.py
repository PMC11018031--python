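"""Synthetic proteome and structure generator with known truth.

Gene families are evolved over a rooted binary species tree under a
Poisson / uniform-replacement substitution model (the protein analogue of
Jukes-Cantor): along a branch of length b each site substitutes with
probability 1 - e^(-b) to a uniformly chosen different residue, so the
expected identity between two leaves at patristic distance d has the closed
form e^(-d) + (1 - e^(-d)) / 19, which makes the generator self-verifying.
Indels are Poisson events with geometric lengths, whole lineages can be
lost, and unrelated decoy sequences provide clean negatives. Structure
fixtures are self-avoiding C-alpha chains perturbed by known rigid motions
plus Gaussian noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .db import ProteinDatabase, Record
from .scoring import AMINO_ACIDS, BACKGROUND
from .structhom import StructureModel

DECOY = "DECOY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    """An i.i.d. random protein with standard background composition.

    Background (not uniform) frequencies matter: uniform sequences
    over-represent rare residues with large self-scores (W, C) and produce
    several-fold more spurious high-scoring local alignments under
    BLOSUM62 than real unrelated proteins do.
    """
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class SpeciesTree:
    """Rooted binary tree over organism labels with branch lengths in
    expected substitutions per site."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for node in self.tree.preorder_node_iter():
            children = node.child_nodes()
            if children and len(children) != 2:
                raise ValueError("tree must be rooted and binary")
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("branch lengths must be non-negative")

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)


def random_species_tree(
    labels: list[str], rng: np.random.Generator, max_branch: float = 0.5,
    min_branch: float = 0.02,
) -> SpeciesTree:
    """Random rooted binary topology with uniform branch lengths."""
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    nodes = [f"'{lbl}'" for lbl in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        ba = rng.uniform(min_branch, max_branch)
        bb = rng.uniform(min_branch, max_branch)
        nodes.append(f"({a}:{ba:.6f},{b}:{bb:.6f})")
    return SpeciesTree.from_newick(nodes[0] + ";")


@dataclass
class FamilySpec:
    """Parameters of one simulated gene family."""

    root_length: int = 200
    indel_rate: float = 0.01
    indel_length_mean: float = 3.0
    loss_prob: float = 0.0
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.root_length < 20:
            raise ValueError("root_length must be >= 20")
        if self.indel_rate < 0 or self.indel_length_mean < 1:
            raise ValueError("invalid indel parameters")
        if not 0 <= self.loss_prob <= 1:
            raise ValueError("loss_prob must be in [0, 1]")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


@dataclass
class SimulatedFamily:
    family_id: str
    sequences: dict[str, str]  # organism -> sequence (surviving leaves only)
    lost: list[str] = field(default_factory=list)


def expected_identity(d: float) -> float:
    """Closed-form expected identity at patristic distance d under the
    uniform-replacement model."""
    return float(np.exp(-d) + (1 - np.exp(-d)) / 19.0)


def _evolve_branch(seq: np.ndarray, b: float, spec: FamilySpec,
                   rng: np.random.Generator) -> np.ndarray:
    seq = seq.copy()
    if b > 0:
        p = 1.0 - np.exp(-b)
        hit = rng.random(len(seq)) < p
        n_hit = int(hit.sum())
        if n_hit:
            # uniform among the 19 other residues
            shift = rng.integers(1, 20, size=n_hit)
            seq[hit] = (seq[hit] + shift) % 20
    n_events = rng.poisson(spec.indel_rate * b * len(seq)) if b > 0 else 0
    for _ in range(n_events):
        if len(seq) <= 20:
            break
        length = int(rng.geometric(1.0 / spec.indel_length_mean))
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5:
            ins = rng.integers(0, 20, size=length).astype(seq.dtype)
            seq = np.concatenate([seq[:pos], ins, seq[pos:]])
        else:
            seq = np.concatenate([seq[:pos], seq[pos + length:]])
    return seq


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def simulate_family(
    tree: SpeciesTree, spec: FamilySpec, family_id: str = "fam0"
) -> SimulatedFamily:
    """Evolve one gene family over the species tree.

    Deterministic given spec.seed. A lineage dropped with probability
    loss_prob (on the branch leading to it) is absent from all its
    descendants.
    """
    rng = np.random.default_rng(spec.seed)
    root_seq = rng.integers(0, 20, size=spec.root_length).astype(np.int16)
    sequences: dict[str, str] = {}
    lost: list[str] = []

    def visit(node, seq):
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            dropped = rng.random() < spec.loss_prob
            child_seq = None if dropped else _evolve_branch(seq, b, spec, rng)
            if dropped:
                for leaf in child.leaf_iter():
                    lost.append(leaf.taxon.label)
            elif child.is_leaf():
                sequences[child.taxon.label] = _decode(child_seq)
            else:
                visit(child, child_seq)

    root = tree.tree.seed_node
    if root.is_leaf():
        raise ValueError("tree must have at least one internal node")
    visit(root, root_seq)
    return SimulatedFamily(family_id=family_id, sequences=sequences, lost=lost)


def emit_database(
    families: list[SimulatedFamily],
    spec: FamilySpec,
    organisms: list[str] | None = None,
) -> tuple[ProteinDatabase, pd.DataFrame]:
    """Assemble a protein database plus its truth table.

    Adds spec.n_decoys i.i.d. background-composition decoy sequences per
    organism, with lengths drawn from the simulated family length
    distribution. The
    truth table has one present=True row per emitted record and one
    present=False row (empty record id) per simulated loss.
    """
    if not families:
        raise ValueError("need at least one simulated family")
    rng = np.random.default_rng(spec.seed + 10**6)
    if organisms is None:
        seen: dict[str, None] = {}
        for fam in families:
            for org in fam.sequences:
                seen.setdefault(org, None)
            for org in fam.lost:
                seen.setdefault(org, None)
        organisms = sorted(seen)
    db = ProteinDatabase()
    rows = []
    fam_lengths = [len(s) for fam in families for s in fam.sequences.values()]
    if not fam_lengths:  # every lineage lost: decoys fall back to root_length
        fam_lengths = [spec.root_length]
    for fam in families:
        for org in organisms:
            if org in fam.sequences:
                rec_id = f"{org}|{fam.family_id}"
                db.add(Record(id=rec_id, organism=org, seq=fam.sequences[org],
                              family=fam.family_id))
                rows.append((org, rec_id, fam.family_id, True))
            elif org in fam.lost:
                rows.append((org, "", fam.family_id, False))
    for org in organisms:
        for k in range(spec.n_decoys):
            length = int(fam_lengths[int(rng.integers(len(fam_lengths)))])
            seq = random_protein(rng, length)
            rec_id = f"{org}|decoy{k}"
            db.add(Record(id=rec_id, organism=org, seq=seq, family=DECOY))
            rows.append((org, rec_id, DECOY, True))
    truth = pd.DataFrame(rows, columns=["organism", "record_id", "family_id", "present"])
    n_present = int(truth["present"].sum())
    assert n_present == len(db), "truth rows must match emitted records"
    return db, truth


def write_outputs(
    db: ProteinDatabase, truth: pd.DataFrame, outdir: str | Path, seed: int
) -> None:
    """One FASTA per organism, a combined FASTA, and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db.to_fasta(outdir / "combined.fasta")
    for org in db.organisms:
        ProteinDatabase(db.by_organism(org)).to_fasta(outdir / f"{org}.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(f"# seed={seed}\n")
        truth.to_csv(fh, sep="\t", index=False)


_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _CODONS.setdefault(aa, []).append(codon)
    return _CODONS


def encode_protein_to_dna(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniformly random synonymous codons."""
    table = _codon_table()
    return "".join(
        table[aa][int(rng.integers(len(table[aa])))] for aa in protein.upper()
    )


def frameshift_fixture(
    seed: int,
    protein_length: int = 150,
    n_shifts: int = 1,
    flank: int = 30,
) -> tuple[str, str]:
    """A contig encoding a known protein, corrupted by 1-nt frameshifts.

    The gene is flanked by stop codons plus random sequence. Shifts are
    single-nucleotide insertions at codon boundaries (a 1-nt deletion
    destroys one codon outright, so exact recovery would be impossible by
    construction; deletions are exercised through the pileup-correction
    path, where read evidence restores the lost base). Shift positions are
    drawn one per equal segment of the gene interior, at least 30 codons
    from either terminus. Returns (contig, truth protein).
    """
    rng = np.random.default_rng(seed)
    protein = "M" + _decode(rng.integers(0, 20, size=protein_length - 1).astype(np.int16))
    dna = encode_protein_to_dna(protein, rng)
    margin = 30
    interior = protein_length - 2 * margin
    if interior < n_shifts:
        raise ValueError("protein too short for the requested shifts")
    width = interior // n_shifts
    if width < 30:
        raise ValueError("protein too short to keep shifts 30 codons apart")
    # one shift per segment, jitter bounded so shifts stay >= 30 codons apart
    jitter = max(1, width - 30 + 1)
    positions = [
        margin + k * width + int(rng.integers(jitter)) for k in range(n_shifts)
    ]
    for codon_pos in sorted(positions, reverse=True):
        nt = 3 * codon_pos
        base = "ACGT"[int(rng.integers(4))]
        dna = dna[:nt] + base + dna[nt:]
    left = encode_protein_to_dna(
        _decode(rng.integers(0, 20, size=flank // 3).astype(np.int16)), rng
    )
    right = encode_protein_to_dna(
        _decode(rng.integers(0, 20, size=flank // 3).astype(np.int16)), rng
    )
    contig = left + "TAA" + dna + "TAA" + right
    return contig, protein


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def self_avoiding_chain(
    n_residues: int, rng: np.random.Generator, step: float = 3.8,
    min_separation: float = 3.6,
) -> np.ndarray:
    """Self-avoiding 3D C-alpha chain with fixed consecutive spacing."""
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        for _ in range(1000):
            v = rng.standard_normal(3)
            v = v / np.linalg.norm(v) * step
            cand = coords[i - 1] + v
            d = np.linalg.norm(coords[: max(0, i - 1)] - cand, axis=1)
            if d.size == 0 or d.min() >= min_separation:
                coords[i] = cand
                break
        else:  # pragma: no cover - practically unreachable in 3D
            raise RuntimeError("chain generation stalled")
    return coords


def simulate_structure_pair(
    n_residues: int, noise_sigma: float, seed: int, sequence: str | None = None
) -> tuple[StructureModel, StructureModel, tuple[np.ndarray, np.ndarray]]:
    """A C-alpha chain and a rigidly moved, noise-perturbed copy.

    B = R A + t + N(0, sigma^2 I3) per atom, R a uniform random rotation.
    Confidence is set to 90 throughout.
    """
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    A = self_avoiding_chain(n_residues, rng)
    R = _random_rotation(rng)
    t = rng.uniform(-50, 50, size=3)
    B = A @ R.T + t
    if noise_sigma > 0:
        B = B + rng.normal(0.0, noise_sigma, size=B.shape)
    if sequence is None:
        sequence = _decode(rng.integers(0, 20, size=n_residues).astype(np.int16))
    conf = np.full(n_residues, 90.0)
    mA = StructureModel("A", A, conf.copy(), sequence)
    mB = StructureModel("B", B, conf.copy(), sequence)
    return mA, mB, (R, t)


def structure_pair_with_rmsd(
    n_residues: int, target_rmsd: float, seed: int, sequence: str | None = None
) -> tuple[StructureModel, StructureModel]:
    """A pair whose post-superposition RMSD equals target_rmsd to ~1e-9,
    never undershooting it.

    The perturbation is projected to remove net translation and rescaled
    iteratively against the measured post-fit RMSD; the iteration aims a
    hair's breadth above the target so that a pair built "at" a strict
    threshold always fails that threshold, as the boundary rules require.
    """
    from .structhom import kabsch_superpose

    mA, mB, _ = simulate_structure_pair(n_residues, 0.0, seed, sequence)
    rng = np.random.default_rng(seed + 1)
    D = rng.standard_normal((n_residues, 3))
    D -= D.mean(axis=0)
    B = mB.coords + D * (target_rmsd / np.sqrt((D**2).sum(axis=1).mean()))
    if target_rmsd > 0:
        aim = target_rmsd * (1 + 1e-12) + 1e-13
        for _ in range(200):
            _, _, r = kabsch_superpose(mA.coords, B)
            if target_rmsd <= r < target_rmsd + 1e-9:
                break
            B = mB.coords + (B - mB.coords) * (aim / r)
    mB2 = StructureModel(mB.model_id, B, mB.confidence.copy(), mB.sequence)
    return mA, mB2
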