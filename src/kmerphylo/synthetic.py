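"""Dinucleotide-biased genome simulator with evolution along a known tree.

A first-order Markov chain over {A, C, G, T} generates a root sequence
whose CG (and/or TA) dinucleotide frequency is suppressed relative to the
independence expectation — the simplest generator exhibiting the CpG/TpA
depletion that pushes CG- and TA-containing 8-mers toward the
low-frequency end of the spectrum. The root is then evolved along a tree
with given branch lengths (expected substitutions per site) under the
Jukes–Cantor model, giving leaf genomes with a known true topology.

The suppression multipliers ``lambda_cg``/``lambda_ta`` scale the C→G and
T→A transition probabilities before row renormalization; 1 means no
suppression, smaller is stronger. No biological mechanism (methylation,
deamination) is modelled — this is a controlled test fixture.

Seeding: one master seed; the root and every tree branch draw from an
independent stream derived deterministically from (seed, node id), so a
run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .genome_io import Genome, GenomeRecord, write_fasta
from .kmer_engine import BASES
from .nj_tree import read_newick, to_newick

__all__ = [
    "SimConfig",
    "markov_transition",
    "stationary_distribution",
    "generate_root",
    "evolve_along_tree",
    "simulate",
    "simulate_to_dir",
    "balanced_tree",
    "random_binary_tree",
]

_A, _C, _G, _T = range(4)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``tree`` is a Newick string with branch lengths in expected
    substitutions per site; its leaf labels name the output taxa.
    """

    tree: str
    root_length: int = 200_000
    gc_target: float = 0.5
    lambda_cg: float = 0.3
    lambda_ta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must lie in (0, 1)")
        for name in ("lambda_cg", "lambda_ta"):
            lam = getattr(self, name)
            if not 0.0 < lam <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]; 1 = no suppression")
        if self.root_length < 2:
            raise ValueError("root_length must be >= 2")


def markov_transition(
    gc_target: float, lambda_cg: float = 1.0, lambda_ta: float = 1.0
) -> np.ndarray:
    """Row-stochastic 4x4 next-base matrix with CG/TA suppression.

    Start from the independence matrix with base probabilities
    A = T = (1 − gc)/2 and C = G = gc/2, multiply the C→G entry by
    ``lambda_cg`` and the T→A entry by ``lambda_ta``, and renormalize
    each row.
    """
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie in (0, 1)")
    for name, lam in (("lambda_cg", lambda_cg), ("lambda_ta", lambda_ta)):
        if not 0.0 < lam <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    at = (1.0 - gc_target) / 2.0
    gc = gc_target / 2.0
    base = np.array([at, gc, gc, at], dtype=np.float64)
    P = np.tile(base, (4, 1))
    P[_C, _G] *= lambda_cg
    P[_T, _A] *= lambda_ta
    P /= P.sum(axis=1, keepdims=True)
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary row vector π with πP = π, by the leading left eigenvector."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _branch_rng(seed: int, node_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, node_id]))


def generate_root(
    length: int, transition: np.ndarray, seed: int, record_id: str = "root"
) -> GenomeRecord:
    """Sample a sequence from the chain; first base from its stationary law."""
    if length < 2:
        raise ValueError("length must be >= 2")
    pi = stationary_distribution(transition)
    cum = np.cumsum(transition, axis=1)
    rng = _branch_rng(seed, 0)
    u = rng.random(length)
    codes = np.empty(length, dtype=np.uint8)
    state = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    codes[0] = state
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        codes[i] = state
    seq = "".join(BASES[c] for c in codes)
    return GenomeRecord(record_id=record_id, sequence=seq)


def _jc_substitute(codes: np.ndarray, branch_length: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor: each site substitutes w.p. (3/4)(1 − e^(−4b/3))."""
    if branch_length < 0:
        raise ValueError("branch lengths must be non-negative")
    p = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    hit = rng.random(codes.size) < p
    # conditional on substituting, the new base is uniform over the other 3
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out = codes.copy()
    out[hit] = (out[hit] + shift) % 4
    return out


def evolve_along_tree(
    root: GenomeRecord, tree: dendropy.Tree, seed: int
) -> dict[str, Genome]:
    """Evolve the root down every branch; return one genome per leaf label."""
    root_codes = np.frombuffer(root.sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    root_codes = lut[root_codes]

    genomes: dict[str, Genome] = {}
    # preorder node ids make the per-branch streams independent of labels
    node_ids = {id(nd): i + 1 for i, nd in enumerate(tree.preorder_node_iter())}
    state: dict[int, np.ndarray] = {id(tree.seed_node): root_codes}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        b = nd.edge.length if nd.edge.length is not None else 0.0
        rng = _branch_rng(seed, node_ids[id(nd)])
        child_codes = _jc_substitute(state[id(nd.parent_node)], float(b), rng)
        state[id(nd)] = child_codes
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else f"leaf{node_ids[id(nd)]}"
            seq = "".join(BASES[c] for c in child_codes)
            genomes[label] = Genome(
                taxon_id=label,
                records=(GenomeRecord(record_id=label, sequence=seq),),
            )
    return genomes


def simulate(cfg: SimConfig) -> tuple[dict[str, Genome], dendropy.Tree]:
    """Generate the root and evolve it along the configured tree."""
    tree = read_newick(cfg.tree)
    P = markov_transition(cfg.gc_target, cfg.lambda_cg, cfg.lambda_ta)
    root = generate_root(cfg.root_length, P, cfg.seed)
    genomes = evolve_along_tree(root, tree, cfg.seed)
    return genomes, tree


def simulate_to_dir(cfg: SimConfig, out_dir: str | os.PathLike) -> list[Path]:
    """Run :func:`simulate` and write one FASTA per leaf, the true tree
    (``true_tree.nwk``) and an echo of all parameters (``config.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, tree = simulate(cfg)
    written = []
    for label in sorted(genomes):
        p = out / f"{label}.fasta"
        write_fasta(genomes[label], p)
        written.append(p)
    tree_path = out / "true_tree.nwk"
    tree_path.write_text(to_newick(tree) + "\n")
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps({
        "tree": cfg.tree,
        "root_length": cfg.root_length,
        "gc_target": cfg.gc_target,
        "lambda_cg": cfg.lambda_cg,
        "lambda_ta": cfg.lambda_ta,
        "seed": cfg.seed,
        "n_taxa": len(genomes),
    }, indent=2) + "\n")
    return written + [tree_path, cfg_path]


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.1,
    max_branch: float = 2.0,
    prefix: str = "T",
) -> dendropy.Tree:
    """Random rooted binary tree with uniform branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; every edge
    gets an independent Uniform(min_branch, max_branch) length. The
    corresponding path-length matrix is additive, so neighbor joining must
    recover the topology exactly.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")

    def sub(names: list[str]) -> str:
        pieces = [f"{nm}:{rng.uniform(min_branch, max_branch):.10f}" for nm in names]
        items = pieces[:]
        while len(items) > 1:
            i = int(rng.integers(len(items)))
            a = items.pop(i)
            j = int(rng.integers(len(items)))
            b = items.pop(j)
            items.append(f"({a},{b}):{rng.uniform(min_branch, max_branch):.10f}")
        return items[0]

    labels = [f"{prefix}{i + 1}" for i in range(n_leaves)]
    newick = f"({sub(labels[: n_leaves // 2])},{sub(labels[n_leaves // 2:])});"
    return read_newick(newick)


def balanced_tree(n_taxa: int, branch_length: float = 0.05,
                  prefix: str = "T") -> str:
    """Newick for a fully balanced binary tree; n_taxa must be a power of 2."""
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of 2 and >= 2")
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{branch_length}"
        half = len(names) // 2
        return f"({build(names[:half])},{build(names[half:])}):{branch_length}"

    half = n_taxa // 2
    return f"({build(labels[:half])},{build(labels[half:])});"
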