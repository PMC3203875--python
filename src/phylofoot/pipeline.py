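"""End-to-end driver: scan -> project -> cluster -> groups -> parsimony
-> patterns.

`run_pipeline` wires the stage modules together with their default
settings; every intermediate is kept on the result object so callers
(CLI, tests, exports) can inspect or re-rank without re-running.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from .alignmap import AlignedSite, Alignment, project
from .homology import (
    HomologGroup,
    HomologyTable,
    SiteCluster,
    build_homolog_groups,
    cluster_redundant,
    join_overlapping,
    singleton_clusters,
)
from .parsimony import (
    CharacterLabeling,
    GainLossEvent,
    SpeciesTree,
    extract_events,
    fitch_reconstruct,
)
from .patterns import Pattern, branch_length_score, mine_patterns
from .pssm import DEFAULT_MIN_MSS, ScoringMatrix, SiteMatch, filter_matrices_by_clade, scan_sequence, to_log_odds


@dataclass
class PipelineResult:
    matches: list[SiteMatch]
    sites: list[AlignedSite]
    clusters: list[SiteCluster]
    groups: dict[Hashable, HomologGroup]
    labeling: CharacterLabeling
    events: list[GainLossEvent]
    patterns: list[Pattern]
    group_bls: dict[Hashable, float] = field(default_factory=dict)


def run_pipeline(
    alignment: Alignment,
    tree: SpeciesTree,
    matrices: Sequence[ScoringMatrix],
    homology: HomologyTable | None = None,
    min_mss: float = DEFAULT_MIN_MSS,
    allowed_groups: set[str] | None = None,
    cluster: bool = True,
    join: str | None = None,
    gains_only: bool = True,
    include_extant: bool = False,
    missing: str = "absent",
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
) -> PipelineResult:
    """Run the complete analysis on one aligned regulatory region.

    Species present in the alignment but absent from the tree are
    skipped during scanning; tree leaves without an alignment row are
    handled per ``missing`` ('absent' or 'exclude').  ``join`` may be
    None (rigid redundancy clustering only), 'same_tf' or 'homologs'
    (relaxed overlap joining); ``cluster=False`` turns clustering off
    entirely (singleton clusters).
    """
    if allowed_groups:
        matrices = filter_matrices_by_clade(list(matrices), allowed_groups)
    matrices = [
        m if m.log_odds is not None
        else to_log_odds(m, background=background, pseudocount=pseudocount)
        for m in matrices
    ]
    matches: list[SiteMatch] = []
    sites: list[AlignedSite] = []
    by_species: dict[str, list[AlignedSite]] = {}
    for species in alignment.species:
        if species not in tree.leaf_ids:
            continue
        seq = alignment.ungapped(species)
        for matrix in matrices:
            if len(seq) < matrix.length:
                continue
            for match in scan_sequence(seq, matrix, min_mss=min_mss,
                                       species=species):
                matches.append(match)
                site = project(alignment, match)
                sites.append(site)
                by_species.setdefault(species, []).append(site)

    clusters: list[SiteCluster] = []
    cid_offset = 0
    for species in sorted(by_species):
        sp_sites = by_species[species]
        if not cluster:
            cl = singleton_clusters(sp_sites)
        elif join is not None:
            cl = join_overlapping(sp_sites, mode=join, table=homology)
        else:
            cl = cluster_redundant(sp_sites, table=homology)
        for c in cl:
            clusters.append(
                SiteCluster(
                    cluster_id=c.cluster_id + cid_offset,
                    species=c.species,
                    combined_name=c.combined_name,
                    members=c.members,
                    s=c.s, e=c.e, l=c.l, strand=c.strand,
                )
            )
        cid_offset += len(cl)

    group_list = build_homolog_groups(clusters, table=homology)
    groups = {g.group_id: g for g in group_list}
    presence = {gid: set(g.species) for gid, g in groups.items()}
    labeling = fitch_reconstruct(
        tree, presence, missing=missing, observed=alignment.species
    )
    events = extract_events(labeling, tree)
    patterns = mine_patterns(
        events, groups, tree, gains_only=gains_only,
        include_extant=include_extant,
    )
    group_bls = {
        gid: branch_length_score(tree, g.species) for gid, g in groups.items()
    }
    return PipelineResult(
        matches=matches,
        sites=sites,
        clusters=clusters,
        groups=groups,
        labeling=labeling,
        events=events,
        patterns=patterns,
        group_bls=group_bls,
    )
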