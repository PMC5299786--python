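"""Synthetic communities with known ground truth for every pipeline stage.

The generator builds a small self-consistent world: a genome x gene
copy-number matrix with block-structured accessory content (genes within a
block co-occur across genomes, so co-occurrence clustering has a recoverable
planted answer), a many-to-many gene-to-pathway annotation with a
controllable shared-gene fraction, and a set of universal single-copy marker
genes (copy number exactly 1 in every genome).

Besides the markers, every genome carries a common *core* of copy-1 genes
(prevalent by construction: copy-number CoV 0) and a fixed number of
accessory blocks (carried by a minority of genomes, so accessory genes have
copy-number CoV above the usual 1.5 prevalence threshold).  Because each
genome carries the same number of equally sized blocks, all genomes have
exactly equal annotated size — the no-confound baseline.

Sample profiles follow the community-average model: the abundance of gene g
in sample s is  depth * avg_copy(g, s) / avg_genome_size(s), where the
averages are taken over the sample's genome (taxa) weights, optionally
perturbed by multiplicative lognormal noise.  ``genome_size_spread`` scales
each genome's accessory content by a per-genome lognormal factor, making
average genome size vary across samples — the confound that relative
normalization cannot remove but single-copy marker normalization can.  The
scaled (float) content matrix is the ground-truth community gene content and
is returned in the sidecar.

Cohort generators plant individual-specific signature genes (for
fingerprinting) or case/control pathway effects with an optional genome-size
confound (for association testing); all generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles_io import (FuncvarError, GeneProfile, GenomeContent, MarkerSet,
                          PathwayMap, SampleMetadata)


@dataclass(frozen=True)
class SyntheticWorld:
    """A reference universe: genomes, annotation, markers, planted structure."""

    content: GenomeContent
    pathway_map: PathwayMap
    markers: MarkerSet
    blocks: dict[str, tuple[str, ...]]   # planted co-occurrence blocks
    core_genes: tuple[str, ...]
    seed: int

    @property
    def marker_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.markers.gene_ids))

    @property
    def block_genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for genes in self.blocks.values():
            out.extend(genes)
        return tuple(sorted(out))

    @property
    def nonmarker_genes(self) -> tuple[str, ...]:
        ms = set(self.markers.gene_ids)
        return tuple(g for g in self.content.gene_ids if g not in ms)


@dataclass(frozen=True)
class ProfileGroundTruth:
    """Sidecar truth for a simulated profile batch."""

    true_copy_number: pd.DataFrame    # samples x genes: avg copies per genome
    taxa_weights: pd.DataFrame        # samples x genomes, rows sum to 1
    effective_copies: pd.DataFrame    # genomes x genes (accessory scaled)
    avg_genome_size: pd.Series        # per sample
    variable_genes: tuple[str, ...]   # planted variable (accessory) genes


@dataclass(frozen=True)
class CohortGroundTruth:
    signatures: dict[str, tuple[str, ...]]   # individual -> signature genes
    signature_strength: float


@dataclass(frozen=True)
class CaseControlGroundTruth:
    affected_pathways: tuple[str, ...]
    affected_genes: tuple[str, ...]
    effect: float
    confound_factor: float | None


def simulate_world(n_genomes: int = 40, n_genes: int = 570,
                   n_pathways: int = 8, n_markers: int = 10,
                   n_core: int = 200, n_blocks: int = 8,
                   blocks_per_genome: int = 2,
                   shared_fraction: float = 0.3,
                   pathway_fidelity: float = 0.7,
                   seed: int = 0) -> SyntheticWorld:
    """Build a seed-deterministic synthetic reference world.

    The accessory genes (everything beyond markers and core) are split into
    ``n_blocks`` equal blocks; each genome carries exactly
    ``blocks_per_genome`` of them (copy 1), so genome sizes are equal and the
    block partition is the planted co-occurrence truth.  The pathway
    annotation covers core + accessory genes, assigning each a primary
    pathway and giving a ``shared_fraction`` of them a second pathway.

    Pathway annotation correlates with genomic structure the way real
    annotations do: each block has a "home" pathway and a block gene's
    primary assignment lands there with probability ``pathway_fidelity``
    (the remainder scatter uniformly), so pathway abundances genuinely vary
    with community composition while still mixing co-occurrence blocks.
    Core genes are assigned round-robin.
    """
    if n_markers < 1:
        raise FuncvarError("need at least one marker gene")
    n_block_genes = n_genes - n_markers - n_core
    if n_block_genes <= 0:
        raise FuncvarError("n_genes must exceed n_markers + n_core")
    if n_block_genes % n_blocks != 0:
        raise FuncvarError(
            f"accessory gene count {n_block_genes} not divisible by "
            f"n_blocks={n_blocks}")
    if not 1 <= blocks_per_genome <= n_blocks:
        raise FuncvarError("blocks_per_genome out of range")
    if not 0 <= shared_fraction <= 1:
        raise FuncvarError("shared_fraction must be in [0, 1]")
    if not 0 <= pathway_fidelity <= 1:
        raise FuncvarError("pathway_fidelity must be in [0, 1]")
    if n_pathways < 1 or n_genomes < 2:
        raise FuncvarError("need >= 1 pathway and >= 2 genomes")
    rng = np.random.default_rng(seed)

    markers = [f"M{i + 1:03d}" for i in range(n_markers)]
    core = [f"C{i + 1:04d}" for i in range(n_core)]
    block_size = n_block_genes // n_blocks
    blocks: dict[str, tuple[str, ...]] = {}
    accessory: list[str] = []
    for b in range(n_blocks):
        genes = tuple(f"K{b * block_size + i + 1:05d}" for i in range(block_size))
        blocks[f"B{b + 1:02d}"] = genes
        accessory.extend(genes)
    genomes = [f"T{i + 1:03d}" for i in range(n_genomes)]

    all_genes = markers + core + accessory
    copies = np.zeros((n_genomes, len(all_genes)), dtype=int)
    copies[:, :n_markers + n_core] = 1
    block_ids = list(blocks)
    gene_pos = {g: j for j, g in enumerate(all_genes)}
    for gi in range(n_genomes):
        carried = rng.choice(n_blocks, size=blocks_per_genome, replace=False)
        for b in carried:
            for g in blocks[block_ids[b]]:
                copies[gi, gene_pos[g]] = 1
    content = GenomeContent(pd.DataFrame(copies, index=genomes, columns=all_genes))

    pathways = [f"P{i + 1:02d}" for i in range(n_pathways)]
    primary_of: dict[str, int] = {}
    for i, gene in enumerate(core):
        primary_of[gene] = i % n_pathways
    for b, genes in enumerate(blocks.values()):
        home = b % n_pathways
        for gene in genes:
            if n_pathways == 1 or rng.random() < pathway_fidelity:
                primary_of[gene] = home
            else:
                offset = 1 + rng.integers(n_pathways - 1)
                primary_of[gene] = (home + offset) % n_pathways
    mapped = core + accessory
    shared_flags = rng.permutation(len(mapped)) < int(
        round(shared_fraction * len(mapped)))
    pairs: list[tuple[str, str]] = []
    for gene, is_shared in zip(mapped, shared_flags):
        primary = primary_of[gene]
        pairs.append((gene, pathways[primary]))
        if is_shared and n_pathways >= 2:
            offset = 1 + rng.integers(n_pathways - 1)
            pairs.append((gene, pathways[(primary + offset) % n_pathways]))
    return SyntheticWorld(content=content, pathway_map=PathwayMap(pairs),
                          markers=MarkerSet.from_ids(markers),
                          blocks=blocks, core_genes=tuple(core), seed=int(seed))


def _lognormal_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Multiplicative lognormal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(sigma * rng.standard_normal(shape) - sigma ** 2 / 2.0)


def _community_base(world: SyntheticWorld, weights: np.ndarray,
                    size_factors: np.ndarray, depth: float
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free abundances from taxa weights and accessory size factors.

    Returns (abundance, true_copy, effective_copies): abundance(s, g) =
    depth * true_copy(s, g) / avg_size(s), with true_copy = weights @ C_eff.
    Markers and core stay copy-exact; accessory content scales per genome.
    """
    genes = world.content.gene_ids
    c_eff = world.content.copies.astype(float)
    acc = np.array([g in set(world.block_genes) for g in genes])
    c_eff[:, acc] = c_eff[:, acc] * size_factors[:, None]
    true_copy = weights @ c_eff
    avg_size = weights @ c_eff.sum(axis=1)
    abundance = depth * true_copy / avg_size[:, None]
    return abundance, true_copy, c_eff


def simulate_profiles(world: SyntheticWorld, n_samples: int = 50,
                      depth: float = 1e6, noise_cv: float = 0.1,
                      genome_size_spread: float = 0.5,
                      dirichlet_alpha: float = 0.5,
                      seed: int = 0) -> tuple[GeneProfile, ProfileGroundTruth]:
    """Simulate sample x gene abundances with known community composition.

    Taxa weights are Dirichlet(alpha) per sample; ``genome_size_spread`` is
    the log-sd of the per-genome accessory scaling factors (0 disables the
    genome-size confound entirely); ``noise_cv`` is the CV of multiplicative
    lognormal measurement noise (0 for noise-free profiles).
    """
    if depth <= 0 or noise_cv < 0 or genome_size_spread < 0:
        raise FuncvarError("depth must be > 0 and spreads >= 0")
    rng = np.random.default_rng(seed)
    n_genomes = len(world.content.genome_ids)
    size_factors = np.exp(genome_size_spread * rng.standard_normal(n_genomes))
    weights = rng.dirichlet(np.full(n_genomes, dirichlet_alpha), size=n_samples)
    base, true_copy, c_eff = _community_base(world, weights, size_factors, depth)
    noise = _lognormal_noise(rng, base.shape, noise_cv)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    genes = world.content.gene_ids
    profile = GeneProfile(pd.DataFrame(base * noise, index=samples, columns=genes))
    truth = ProfileGroundTruth(
        true_copy_number=pd.DataFrame(true_copy, index=samples, columns=genes),
        taxa_weights=pd.DataFrame(weights, index=samples,
                                  columns=world.content.genome_ids),
        effective_copies=pd.DataFrame(c_eff, index=world.content.genome_ids,
                                      columns=genes),
        avg_genome_size=pd.Series((weights @ c_eff.sum(axis=1)), index=samples),
        variable_genes=world.block_genes)
    return profile, truth


def simulate_two_visit_cohort(world: SyntheticWorld, n_individuals: int = 36,
                              signature_strength: float = 10.0,
                              n_signature_genes: int = 25,
                              noise_cv: float = 0.1,
                              genome_size_spread: float = 0.0,
                              dirichlet_alpha: float = 0.5,
                              depth: float = 1e6, seed: int = 0
                              ) -> tuple[GeneProfile, GeneProfile,
                                         SampleMetadata, CohortGroundTruth]:
    """Two visits per individual with persistent private signature genes.

    Each individual receives a disjoint set of accessory signature genes whose
    abundance is boosted by ``signature_strength`` times the individual's mean
    gene abundance at *both* visits; the background community is regenerated
    independently per visit, so with ``signature_strength=0`` there is no
    individual-specific signal at all (the identification null).
    """
    if n_individuals < 2:
        raise FuncvarError("need >= 2 individuals")
    if signature_strength < 0:
        raise FuncvarError("signature_strength must be >= 0")
    pool = list(world.block_genes)
    need = n_individuals * n_signature_genes
    if need > len(pool):
        raise FuncvarError(
            f"world has {len(pool)} accessory genes but "
            f"{need} signature genes are required; build a larger world")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(pool))[:need]
    individuals = [f"I{i + 1:03d}" for i in range(n_individuals)]
    signatures = {
        ind: tuple(sorted(pool[j] for j in
                          chosen[i * n_signature_genes:(i + 1) * n_signature_genes]))
        for i, ind in enumerate(individuals)}

    n_genomes = len(world.content.genome_ids)
    genes = world.content.gene_ids
    gene_pos = {g: j for j, g in enumerate(genes)}
    size_factors = np.exp(genome_size_spread * rng.standard_normal(n_genomes))
    profiles = []
    for visit in (1, 2):
        weights = rng.dirichlet(np.full(n_genomes, dirichlet_alpha),
                                size=n_individuals)
        base, _, _ = _community_base(world, weights, size_factors, depth)
        for i, ind in enumerate(individuals):
            boost = signature_strength * base[i].mean()
            for g in signatures[ind]:
                base[i, gene_pos[g]] += boost
        base *= _lognormal_noise(rng, base.shape, noise_cv)
        samples = [f"{ind}_v{visit}" for ind in individuals]
        profiles.append(GeneProfile(pd.DataFrame(base, index=samples,
                                                 columns=genes)))
    meta_rows = []
    for visit in (1, 2):
        for ind in individuals:
            meta_rows.append((f"{ind}_v{visit}", ind, visit))
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, columns=["sample_id", "individual_id", "visit"]
    ).set_index("sample_id"))
    truth = CohortGroundTruth(signatures, float(signature_strength))
    return profiles[0], profiles[1], meta, truth


def simulate_case_control(world: SyntheticWorld, n_case: int = 25,
                          n_control: int = 25,
                          affected_pathways: list[str] | int | None = 1,
                          effect: float = 2.0,
                          confound_genome_size: bool = False,
                          confound_factor: float | None = None,
                          noise_cv: float = 0.1,
                          dirichlet_alpha: float = 0.5,
                          depth: float = 1e6, seed: int = 0
                          ) -> tuple[GeneProfile, SampleMetadata,
                                     CaseControlGroundTruth]:
    """Case/control cohort with a planted pathway-level effect.

    Genes of the affected pathway(s) are multiplied by ``effect`` in case
    samples.  With ``confound_genome_size=True`` the cases' remaining
    non-marker gene content is multiplied by ``confound_factor`` (defaulting
    to ``effect``), so case totals scale with the effect and relative
    normalization cancels the planted shift while the single-copy marker
    yardstick — which is deliberately left unscaled — does not.
    """
    if effect < 0:
        raise FuncvarError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    pathways = sorted(world.pathway_map.pathways)
    if affected_pathways is None:
        affected_pathways = 1
    if isinstance(affected_pathways, int):
        idx = rng.choice(len(pathways), size=affected_pathways, replace=False)
        affected = tuple(sorted(pathways[i] for i in idx))
    else:
        unknown = set(affected_pathways) - set(pathways)
        if unknown:
            raise FuncvarError(f"unknown pathway(s): {sorted(unknown)}")
        affected = tuple(sorted(affected_pathways))
    affected_genes: set[str] = set()
    for p in affected:
        affected_genes |= world.pathway_map.genes_of(p)

    n = n_case + n_control
    n_genomes = len(world.content.genome_ids)
    genes = world.content.gene_ids
    weights = rng.dirichlet(np.full(n_genomes, dirichlet_alpha), size=n)
    base, _, _ = _community_base(world, weights, np.ones(n_genomes), depth)
    aff_mask = np.array([g in affected_genes for g in genes])
    marker_mask = np.array([g in world.markers.gene_ids for g in genes])
    base[:n_case, aff_mask] *= effect
    if confound_genome_size:
        factor = effect if confound_factor is None else confound_factor
        other = ~aff_mask & ~marker_mask
        base[:n_case, other] *= factor
    else:
        factor = None
    base *= _lognormal_noise(rng, base.shape, noise_cv)
    samples = ([f"case{i + 1:03d}" for i in range(n_case)]
               + [f"ctrl{i + 1:03d}" for i in range(n_control)])
    profile = GeneProfile(pd.DataFrame(base, index=samples, columns=genes))
    meta = SampleMetadata(pd.DataFrame({
        "individual_id": samples,
        "visit": np.ones(n, dtype=int),
        "group": ["case"] * n_case + ["control"] * n_control,
    }, index=pd.Index(samples, name="sample_id")))
    truth = CaseControlGroundTruth(affected, tuple(sorted(affected_genes)),
                                   float(effect),
                                   None if factor is None else float(factor))
    return profile, meta, truth
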