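"""Ortholog tables (reciprocal best hit), gene-class assignment, and
composite (fusion) gene annotation.

Homology here is alignment-based: proteins are paired across proteomes
by reciprocal best global-alignment score (RBH), with a shared-k-mer
prescreen to avoid the full all-vs-all alignment cost.  Gene classes —
core / lepidopteran-shared / GV-specific / unique — are derived from
presence patterns across user-defined genome panels (genera).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align as _align

__all__ = [
    "OrthologTable",
    "GeneClassTable",
    "FusionAnnotation",
    "reciprocal_best_hits",
    "build_ortholog_table",
    "classify_families",
    "annotate_fusion",
]


@dataclass
class OrthologTable:
    """Family membership across genomes: family id -> {genome: protein id}."""

    genomes: list[str]
    families: dict[str, dict[str, str]] = field(default_factory=dict)
    pair_identity: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def members(self, family: str) -> dict[str, str]:
        return self.families[family]

    def presence(self, family: str) -> set[str]:
        return set(self.families[family])


@dataclass
class GeneClassTable:
    """Per-gene class: core / lepidopteran / gv_specific / unique / other."""

    classes: dict[str, str]
    counts: dict[str, int]


@dataclass
class FusionAnnotation:
    """Domain layout of a composite protein, in 1-based aa coordinates."""

    protein_id: str
    segments: list[tuple[str, int, int]]  # (domain, aa start, aa end)
    linker: tuple[int, int] | None
    total_aa: int

    @property
    def linker_length(self) -> int:
        if self.linker is None:
            return 0
        return self.linker[1] - self.linker[0] + 1


def _kmer_set(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def reciprocal_best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
                         params: _align.AlignParams | None = None,
                         score_floor: float = 0.0, k: int = 4,
                         prescreen_top: int = 10) -> list[tuple[str, str, float]]:
    """Pairs (a, b, identity) where each is the other's best-scoring match.

    Candidate partners are ranked by shared k-mer count and only the top
    ``prescreen_top`` are aligned.  Ties in score break by higher
    identity, then id order, so output is deterministic and symmetric.
    """
    if not proteome_a or not proteome_b:
        return []
    if params is None:
        params = _align.PROTEIN_DEFAULT
    kmers_a = {i: _kmer_set(s, k) for i, s in proteome_a.items()}
    kmers_b = {i: _kmer_set(s, k) for i, s in proteome_b.items()}

    def best_hits(src, dst, km_src, km_dst):
        best = {}
        for ida in sorted(src):
            ranked = sorted(
                dst,
                key=lambda idb: (-len(km_src[ida] & km_dst[idb]), idb),
            )[:prescreen_top]
            top = None
            for idb in ranked:
                al = _align.global_align(src[ida], dst[idb], params)
                ident = _align.percent_identity(al, "aligned_columns")
                # deterministic: higher score, then identity, then id order
                if (top is None or (al.score, ident) > (top[0], top[1])
                        or ((al.score, ident) == (top[0], top[1])
                            and idb < top[2])):
                    top = (al.score, ident, idb)
            if top is not None and top[0] >= score_floor:
                best[ida] = (top[2], top[1])
        return best

    ab = best_hits(proteome_a, proteome_b, kmers_a, kmers_b)
    ba = best_hits(proteome_b, proteome_a, kmers_b, kmers_a)
    pairs = []
    for ida, (idb, ident) in sorted(ab.items()):
        if ba.get(idb, (None,))[0] == ida:
            pairs.append((ida, idb, ident))
    return pairs


def build_ortholog_table(proteomes: dict[str, dict[str, str]],
                         reference: str | None = None,
                         params: _align.AlignParams | None = None,
                         score_floor: float = 0.0) -> OrthologTable:
    """Star-shaped ortholog table: RBH of every genome against a reference.

    The reference (default: first genome id in sorted order) anchors the
    families; family ids are the reference protein ids.
    """
    genomes = sorted(proteomes)
    if reference is None:
        reference = genomes[0]
    table = OrthologTable(genomes=genomes)
    for pid in sorted(proteomes[reference]):
        table.families[pid] = {reference: pid}
    for other in genomes:
        if other == reference:
            continue
        pairs = reciprocal_best_hits(proteomes[reference], proteomes[other],
                                     params, score_floor)
        for ida, idb, ident in pairs:
            table.families[ida][other] = idb
            table.pair_identity[(ida, reference, other)] = ident
    return table


def classify_families(table: OrthologTable, panels: dict[str, list[str]],
                      focal: str,
                      beta_panel: str = "betabaculovirus") -> GeneClassTable:
    """Assign a class to every family from its presence pattern.

    ``panels`` maps panel (genus) names to genome id lists and must
    cover every genome in the table.  core = present in all genomes of
    all panels; unique = present only in the focal genome; gv_specific =
    present in >= 1 genome of the betabaculovirus panel and absent from
    every other panel; lepidopteran = present in all lepidopteran-infecting
    panels (betabaculovirus + alphabaculovirus) but not in all panels;
    everything else = other.
    """
    if not panels or any(not v for v in panels.values()):
        raise ValueError("panels must be non-empty genome groupings")
    all_genomes = {gid for v in panels.values() for gid in v}
    missing = set(table.genomes) - all_genomes
    if missing:
        raise ValueError(f"genomes not covered by panels: {sorted(missing)}")
    lep_panels = {p for p in panels if p in (beta_panel, "alphabaculovirus")}
    classes = {}
    for fam in sorted(table.families):
        present = table.presence(fam)
        if present == {focal}:
            cls = "unique"
        elif all(set(panels[p]) <= present for p in panels):
            cls = "core"
        elif present <= set(panels.get(beta_panel, [])) and len(present) >= 1:
            cls = "gv_specific"
        elif lep_panels and all(
            present & set(panels[p]) for p in lep_panels
        ):
            cls = "lepidopteran"
        else:
            cls = "other"
        classes[fam] = cls
    counts: dict[str, int] = {}
    for c in classes.values():
        counts[c] = counts.get(c, 0) + 1
    return GeneClassTable(classes=classes, counts=counts)


def annotate_fusion(protein: str, domains: dict[str, str],
                    protein_id: str = "composite",
                    params: _align.AlignParams | None = None,
                    score_floor: float = 0.0) -> FusionAnnotation:
    """Locate reference domains inside a composite protein.

    Each domain is aligned locally to the protein; the best-scoring
    placement gives its segment span.  The unassigned stretch between
    two located segments is reported as the linker.  A domain that does
    not align above ``score_floor`` is reported absent (omitted), not an
    error.
    """
    from Bio import Align as _bioalign
    from Bio.Align import substitution_matrices

    if params is None:
        params = _align.PROTEIN_DEFAULT
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "local"
    if params.matrix_name == "simple":
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load(
            params.matrix_name)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend

    segments = []
    for name in sorted(domains):
        dom = domains[name]
        result = aligner.align(protein, dom)
        if result.score < score_floor or len(result) == 0:
            continue
        best = result[0]
        t_start = int(best.aligned[0][0][0])
        t_end = int(best.aligned[0][-1][1])
        segments.append((name, t_start + 1, t_end))
    segments.sort(key=lambda s: s[1])
    linker = None
    if len(segments) >= 2:
        gap_start = segments[0][2] + 1
        gap_end = segments[1][1] - 1
        if gap_end >= gap_start:
            linker = (gap_start, gap_end)
    return FusionAnnotation(protein_id=protein_id, segments=segments,
                            linker=linker, total_aa=len(protein))
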