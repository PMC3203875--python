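"""Synthetic data: random species trees and planted gain/loss scenarios.

The generator emulates the structure the method assumes: a module of
motifs is gained at an internal node of the species tree, so every
descendant leaf carries exact consensus copies of the member motifs at
fixed start-to-start spacings, embedded in i.i.d. uniform background
sequence.  Sequences share one coordinate frame (a gapless alignment),
so planted columns are shared across species by construction.  A noise
rate deletes or shifts single members in single leaves, breaking the
module there.  Everything is driven by one integer seed and regenerates
byte-identically (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignmap import Alignment, write_fasta_alignment
from .exceptions import ParameterError
from .parsimony import SpeciesTree, parse_newick
from .pssm import BASES, ScoringMatrix, write_jaspar

#: Digit-free motif names: numbers are stripped during redundancy
#: clustering, so numbered names would alias distinct planted motifs.
MOTIF_NAMES = [
    "Alpha", "Bravo", "Carol", "Delta", "Echo", "Fox", "Golf", "Hotel",
    "India", "Julia", "Kilo", "Lima", "Mike", "Nov", "Oscar", "Papa",
    "Quebec", "Romeo", "Sierra", "Tango", "Uniform", "Victor", "Whisk",
    "Xray", "Yankee", "Zulu",
]

DEFAULT_MOTIF_LENGTH = 8
DEFAULT_BRANCH_LENGTH_RANGE = (0.05, 0.5)


def make_tree(
    n_leaves: int,
    seed: int,
    bl_range: tuple[float, float] = DEFAULT_BRANCH_LENGTH_RANGE,
) -> SpeciesTree:
    """Random rooted binary tree with uniform branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; leaves are
    named sp01..spNN.  Same seed, same Newick text.
    """
    if n_leaves < 2:
        raise ParameterError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    lo, hi = bl_range
    parts = [f"sp{i + 1:02d}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        bl_a, bl_b = rng.uniform(lo, hi, size=2)
        parts.append(f"({a}:{bl_a:.4f},{b}:{bl_b:.4f})")
    return parse_newick(parts[0] + ";")


@dataclass(frozen=True)
class PlantedModule:
    """Ground truth for one planted module."""

    origin_node: int
    origin_name: str
    member_names: tuple[str, ...]
    member_matrix_ids: tuple[str, ...]
    consensi: tuple[str, ...]
    starts: tuple[int, ...]  # 1-based, shared coordinate frame
    spacings: tuple[int, ...]
    species: frozenset[str]  # descendant leaves of the origin
    broken_species: frozenset[str]  # leaves where noise broke the module


@dataclass
class PlantedScenario:
    """A complete synthetic input set with its ground truth."""

    tree: SpeciesTree
    alignment: Alignment
    matrices: list[ScoringMatrix]
    modules: list[PlantedModule]
    seed: int
    region_length: int
    noise_rate: float = 0.0

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(self.tree.newick() + "\n")
        (outdir / "alignment.fasta").write_text(
            write_fasta_alignment(self.alignment)
        )
        (outdir / "matrices.jaspar").write_text(write_jaspar(self.matrices))
        lines = ["module\torigin_node\tmembers\tstarts\tspacings\tspecies\tbroken"]
        for i, m in enumerate(self.modules, start=1):
            lines.append(
                "\t".join([
                    str(i), m.origin_name, ",".join(m.member_names),
                    ",".join(map(str, m.starts)),
                    ",".join(map(str, m.spacings)),
                    ",".join(sorted(m.species)),
                    ",".join(sorted(m.broken_species)),
                ])
            )
        (outdir / "truth.tsv").write_text("\n".join(lines) + "\n")


_RC = str.maketrans("ACGT", "TGCA")


def _scrub_chance_occurrences(
    seqs: dict[str, list[str]],
    modules: list["PlantedModule"],
    intentional: dict[str, list[tuple[int, int]]],
    motif_length: int,
    rng: np.random.Generator,
) -> None:
    """Mutate away chance exact copies of planted consensi.

    A planted consensus occurring by chance in the background of some
    leaf (either strand) would be indistinguishable from a planted site
    and make recovery non-identifiable; one base of each such copy,
    outside every intentional span, is changed.
    """
    patterns = set()
    for m in modules:
        for c in m.consensi:
            patterns.add(c)
            patterns.add(c.translate(_RC)[::-1])
    for _ in range(3):
        dirty = False
        for sp in sorted(seqs):
            chars = seqs[sp]
            spans = intentional.get(sp, [])
            seq = "".join(chars)
            for pat in sorted(patterns):
                start = seq.find(pat)
                while start != -1:
                    if (start, start + motif_length) not in spans:
                        pos = next(
                            (p for p in range(start, start + motif_length)
                             if not any(a <= p < b for a, b in spans)),
                            None,
                        )
                        if pos is not None:
                            others = [b for b in BASES if b != chars[pos]]
                            chars[pos] = others[int(rng.integers(0, 3))]
                            dirty = True
                            seq = "".join(chars)
                    start = seq.find(pat, start + 1)
        if not dirty:
            break


def _random_motif(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _one_hot_matrix(matrix_id: str, name: str, consensus: str,
                    weight: float = 20.0) -> ScoringMatrix:
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, BASES.index(b)] = weight
    return ScoringMatrix(
        matrix_id=matrix_id, tf_name=name, source="user", counts=counts,
        taxon_group="synthetic",
    )


def plant_modules(
    tree: SpeciesTree,
    n_modules: int = 2,
    sizes: tuple[int, ...] = (3,),
    spacing_range: tuple[int, int] = (10, 18),
    noise_rate: float = 0.0,
    seed: int = 0,
    region_length: int = 300,
    motif_length: int = DEFAULT_MOTIF_LENGTH,
) -> PlantedScenario:
    """Plant ``n_modules`` modules (member counts cycled from ``sizes``)
    at random non-root internal nodes.

    Start-to-start spacings are drawn once per consecutive pair from
    ``spacing_range`` (minimum the motif length, so members never
    overlap) and are identical in every carrying leaf.  With probability
    ``noise_rate`` per (module, descendant leaf), one member is deleted
    or shifted by 1-3 bp, breaking the module in that leaf.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise ParameterError("noise_rate must be in [0, 1)")
    if any(s < 1 or s > 6 for s in sizes):
        raise ParameterError("module sizes must be within 1..6")
    rng = np.random.default_rng(seed)
    internal = [v for v in range(1, tree.n_nodes) if not tree.is_leaf(v)]
    if not internal:
        raise ParameterError("tree has no non-root internal node to plant at")
    leaves = tree.leaf_names

    module_sizes = [sizes[i % len(sizes)] for i in range(n_modules)]
    lo_sp = max(spacing_range[0], motif_length)
    hi_sp = max(spacing_range[1], lo_sp)

    # allocate disjoint spans, with margins, along the shared frame
    spans = []
    cursor = 10
    plans = []
    for size in module_sizes:
        spacings = tuple(int(rng.integers(lo_sp, hi_sp + 1))
                         for _ in range(size - 1))
        span = sum(spacings) + motif_length
        starts = tuple(cursor + int(np.sum(spacings[:k]))
                       for k in range(size))
        plans.append((size, spacings, starts))
        spans.append((cursor, cursor + span))
        cursor += span + 15
    if cursor - 15 > region_length:
        raise ParameterError(
            f"region of {region_length} bp too short for the requested "
            f"modules (need {cursor - 15})"
        )

    seqs = {
        sp: list(_random_motif(rng, region_length)) for sp in leaves
    }
    intentional: dict[str, list[tuple[int, int]]] = {}
    matrices: list[ScoringMatrix] = []
    modules: list[PlantedModule] = []
    name_i = 0
    # distinct origins when possible: two modules planted at one node are
    # indistinguishable from a single larger module
    if len(internal) >= len(plans):
        origins = list(rng.choice(internal, size=len(plans), replace=False))
    else:
        origins = [internal[int(rng.integers(0, len(internal)))]
                   for _ in plans]
    for mi, (size, spacings, starts) in enumerate(plans):
        origin = int(origins[mi])
        descendants = tree.descendant_leaves(origin)
        names, mids, consensi = [], [], []
        for _ in range(size):
            name = MOTIF_NAMES[name_i % len(MOTIF_NAMES)]
            if name_i >= len(MOTIF_NAMES):
                name = name + "x" * (name_i // len(MOTIF_NAMES))
            name_i += 1
            consensus = _random_motif(rng, motif_length)
            names.append(name)
            mids.append(f"SYN{name_i:03d}")
            consensi.append(consensus)
            matrices.append(_one_hot_matrix(mids[-1], name, consensus))
        broken: set[str] = set()
        for sp in sorted(descendants):
            planted_at = {}
            for k, start in enumerate(starts):
                seqs[sp][start - 1 : start - 1 + motif_length] = list(consensi[k])
                planted_at[k] = start
            if noise_rate > 0 and rng.random() < noise_rate:
                k = int(rng.integers(0, size))
                start = starts[k]
                # restore background over the planted member
                seqs[sp][start - 1 : start - 1 + motif_length] = list(
                    _random_motif(rng, motif_length)
                )
                del planted_at[k]
                if rng.random() < 0.5 and size > 1:
                    shift = int(rng.integers(1, 4)) * (
                        1 if rng.random() < 0.5 else -1
                    )
                    new_start = min(max(start + shift, 1),
                                    region_length - motif_length + 1)
                    seqs[sp][new_start - 1 : new_start - 1 + motif_length] = (
                        list(consensi[k])
                    )
                    planted_at[k] = new_start
                broken.add(sp)
            for k, start in planted_at.items():
                intentional.setdefault(sp, []).append(
                    (start - 1, start - 1 + motif_length)
                )
        modules.append(
            PlantedModule(
                origin_node=origin,
                origin_name=tree.names[origin],
                member_names=tuple(names),
                member_matrix_ids=tuple(mids),
                consensi=tuple(consensi),
                starts=starts,
                spacings=spacings,
                species=descendants,
                broken_species=frozenset(broken),
            )
        )
    _scrub_chance_occurrences(seqs, modules, intentional, motif_length, rng)
    alignment = Alignment([(sp, "".join(seqs[sp])) for sp in leaves])
    return PlantedScenario(
        tree=tree,
        alignment=alignment,
        matrices=matrices,
        modules=modules,
        seed=seed,
        region_length=region_length,
        noise_rate=noise_rate,
    )
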