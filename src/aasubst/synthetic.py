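"""Synthetic substitution models, model families, trees, and fixture sets.

These generators stand in for curated model collections and real protein
data so that every pipeline stage — cataloguing, distance clustering,
simulation, and model selection — runs offline and deterministically.

A *model family* mimics a taxonomic group of empirical models: one random
base model plus small multiplicative perturbations of it.  Exchangeabilities
are drawn from a log-normal law (median 1, sigma 1 by default), whose heavy
right tail mirrors the rate spread of published amino-acid matrices;
frequencies come from a symmetric Dirichlet whose concentration (default 5)
gives a composition spread comparable to real proteomes.  Perturbation is
multiplicative log-normal on the normalized rates — positivity is preserved
without clipping — and frequencies are resampled from a Dirichlet centered
at the base composition with concentration ``1/epsilon``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .models import AMINO_ACIDS, ModelRecord, MatrixKind, RateModel, TaxonomicGroup
from .distance import normalize_rates
from .paml import write_paml
from .registry import save_catalog
from .simulate import SimulationSpec, simulate_alignment, write_fasta
from .ratematrix import discrete_gamma
from .trees import Phylogeny, parse_newick, write_newick

RateLaw = Callable[[np.random.Generator, int], np.ndarray]


def _lognormal_law(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=1.0, size=size)


@dataclass
class ModelFamilySpec:
    """Layout of a synthetic model catalog: families of perturbed base models."""

    n_families: int = 4
    members_per_family: int = 4
    base_seed: int = 1
    perturbation_scale: float = 0.05
    frequency_concentration: float = 5.0
    rate_distribution: RateLaw = field(default=_lognormal_law)

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbation_scale < 1.0:
            raise ValueError("perturbation scale must lie in [0, 1)")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member")
        if self.frequency_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")


@dataclass
class TreeSpec:
    """Random-tree parameters: taxon count and branch-length law."""

    n_taxa: int
    seed: int = 0
    brlen_law: str = "exponential"  # or "uniform"
    brlen_mean: float = 0.1

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.brlen_law not in ("exponential", "uniform"):
            raise ValueError(f"unknown branch-length law {self.brlen_law!r}")
        if self.brlen_mean <= 0:
            raise ValueError("branch-length mean must be positive")


def random_model(alphabet=AMINO_ACIDS, seed: int = 0,
                 frequency_concentration: float = 5.0,
                 rate_distribution: RateLaw = _lognormal_law,
                 name: str | None = None) -> RateModel:
    """Draw a random reversible model: i.i.d. positive exchangeabilities per
    unordered pair, Dirichlet equilibrium frequencies."""
    alphabet = tuple(alphabet)
    n = len(alphabet)
    rng = np.random.default_rng(seed)
    n_pairs = n * (n - 1) // 2
    rates = rate_distribution(rng, n_pairs)
    if np.any(rates <= 0):
        raise ValueError("rate distribution must produce strictly positive draws")
    M = np.zeros((n, n))
    M[np.tril_indices(n, k=-1)] = rates
    M = M + M.T
    f = rng.dirichlet(np.full(n, frequency_concentration))
    return RateModel(alphabet=alphabet, M=M, f=f,
                     name=name or f"synthetic_s{seed}")


def perturb_model(base: RateModel, epsilon: float, seed: int = 0,
                  name: str | None = None) -> RateModel:
    """Small random relative of ``base``: rates jittered by ``exp(eps * z)``,
    frequencies Dirichlet-resampled around ``base.f`` with concentration
    ``1/eps``.  ``epsilon = 0`` returns an exact copy."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    name = name or f"{base.name}_p{seed}"
    if epsilon == 0.0:
        return base.copy(name=name)
    rng = np.random.default_rng(seed)
    normed = normalize_rates(base)
    n = base.n
    tril = np.tril_indices(n, k=-1)
    jitter = np.exp(epsilon * rng.standard_normal(len(tril[0])))
    M = np.zeros((n, n))
    M[tril] = normed.M[tril] * jitter
    M = M + M.T
    f = rng.dirichlet(base.f / epsilon)
    return RateModel(alphabet=base.alphabet, M=M, f=f, name=name)


def model_family(spec: ModelFamilySpec, family_index: int,
                 alphabet=AMINO_ACIDS) -> list[RateModel]:
    """The base model of family ``family_index`` plus its perturbed members."""
    base_seed = int(np.random.default_rng([spec.base_seed, family_index]).integers(2**31))
    base = random_model(
        alphabet=alphabet, seed=base_seed,
        frequency_concentration=spec.frequency_concentration,
        rate_distribution=spec.rate_distribution,
        name=f"fam{family_index}_m0",
    )
    members = [base]
    for m in range(1, spec.members_per_family):
        member_seed = int(
            np.random.default_rng([spec.base_seed, family_index, m]).integers(2**31)
        )
        members.append(
            perturb_model(base, spec.perturbation_scale, seed=member_seed,
                          name=f"fam{family_index}_m{m}")
        )
    return members


def random_tree(spec: TreeSpec) -> Phylogeny:
    """Random rooted binary tree by sequential random attachment.

    Leaves are named ``T1..Tn``; branch lengths are i.i.d. positive draws
    from the spec's law (exponential with the given mean, or uniform on
    ``(0, 2 * mean)``).
    """
    rng = np.random.default_rng(spec.seed)

    def draw_len() -> float:
        while True:
            if spec.brlen_law == "exponential":
                x = rng.exponential(spec.brlen_mean)
            else:
                x = rng.uniform(0.0, 2.0 * spec.brlen_mean)
            if x > 0.0:
                return x

    # Nodes as nested lists: [left, right] or leaf name; lengths in a dict.
    class _N:
        __slots__ = ("children", "name", "length")

        def __init__(self, name=None):
            self.children = []
            self.name = name
            self.length = 0.0

    root = _N()
    first, second = _N("T1"), _N("T2")
    root.children = [first, second]
    edges = [first, second]
    for i in range(3, spec.n_taxa + 1):
        target = edges[rng.integers(len(edges))]
        # Split target's edge: new internal node takes target and the new leaf.
        inner = _N()
        leaf = _N(f"T{i}")
        inner.children = [target, leaf]
        parent = _find_parent(root, target)
        parent.children[parent.children.index(target)] = inner
        edges.extend([inner, leaf])
    for node in edges:
        node.length = draw_len()

    def to_newick(node: _N) -> str:
        if node.name is not None:
            return f"{node.name}:{node.length:.17g}"
        inner = ",".join(to_newick(c) for c in node.children)
        return f"({inner}):{node.length:.17g}"

    newick = "(" + ",".join(to_newick(c) for c in root.children) + ");"
    return parse_newick(newick)


def _find_parent(node, target):
    for child in node.children:
        if child is target:
            return node
        if child.name is None:
            found = _find_parent(child, target)
            if found is not None:
                return found
    return None


_GROUP_CYCLE = (
    TaxonomicGroup.NUCLEAR_GENERAL,
    TaxonomicGroup.MITOCHONDRIAL,
    TaxonomicGroup.CHLOROPLAST,
    TaxonomicGroup.VIRAL,
    TaxonomicGroup.NUCLEAR_TAXON_SPECIFIC,
    TaxonomicGroup.OTHER,
)


def family_records(spec: ModelFamilySpec, alphabet=AMINO_ACIDS) -> list[ModelRecord]:
    """Catalog records for all families, each family labeled with one
    taxonomic group (cycling through the available groups)."""
    records = []
    for g in range(spec.n_families):
        group = _GROUP_CYCLE[g % len(_GROUP_CYCLE)]
        for model in model_family(spec, g, alphabet=alphabet):
            records.append(
                ModelRecord(
                    model=model, kind=MatrixKind.RATE, taxonomic_group=group,
                    year=2000 + g, authors="synthetic",
                    reference="generated fixture", comments=f"family {g}",
                )
            )
    return records


def make_fixture_set(out_dir: str | Path, spec: ModelFamilySpec | None = None,
                     tree_taxa: int = 12, alignment_sites: int = 300,
                     alphabet=AMINO_ACIDS) -> Path:
    """Write a complete offline fixture set: model catalog (PAML + metadata
    TSV), a Newick tree, a simulated alignment, and a manifest of seeds.

    Regenerating with the same spec reproduces every file byte-for-byte.
    """
    spec = spec or ModelFamilySpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = family_records(spec, alphabet=alphabet)
    save_catalog(records, out_dir / "models")

    tree_seed = int(np.random.default_rng([spec.base_seed, 10_001]).integers(2**31))
    tree = random_tree(TreeSpec(n_taxa=tree_taxa, seed=tree_seed))
    (out_dir / "tree.nwk").write_text(write_newick(tree))

    sim_seed = int(np.random.default_rng([spec.base_seed, 10_002]).integers(2**31))
    sim = SimulationSpec(
        model=records[0].model, tree=tree, het=discrete_gamma(0.5, 4),
        root_sequence="equilibrium", length=alignment_sites,
        replicates=1, seed=sim_seed,
    )
    aln = simulate_alignment(sim)[0]
    write_fasta(aln, out_dir / "alignment.fasta")

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["artifact", "seed", "parameters"])
        writer.writerow(["models", spec.base_seed,
                         f"families={spec.n_families} members={spec.members_per_family} "
                         f"epsilon={spec.perturbation_scale} "
                         f"concentration={spec.frequency_concentration}"])
        writer.writerow(["tree.nwk", tree_seed, f"n_taxa={tree_taxa}"])
        writer.writerow(["alignment.fasta", sim_seed,
                         f"sites={alignment_sites} alpha=0.5 k=4 model={records[0].name}"])
    return manifest
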