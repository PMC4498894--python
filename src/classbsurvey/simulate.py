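"""Synthetic Class B monooxygenase surveys with known ground truth.

Every pipeline stage is testable without downloads by simulating what the
real survey assumes about its data: protein families defined by conserved
fingerprint architectures, evolved along a shared phylogeny, mixed with
motif-free background sequences.

The generator plants the family clades on one tree.  All families descend
from a single ancestral sequence carrying the two Rossmann motifs; at each
family clade root the family's diagnostic fingerprints are installed
(modelling motif gain/divergence on the stem), and from there on the
constrained motif positions evolve only within their allowed residue sets,
so every leaf provably retains its family architecture.  Unconstrained sites
substitute under a site-independent Poisson-type process: along a branch of
length ``b`` each site changes with probability ``1 − exp(−rate·b)``, and a
changed site draws a uniformly random different residue.  There are no
indels, so the true alignment is the ungapped site matrix.

In the default ``nested`` layout the BVMO and NMO clades sit inside an
FMO-dominated backbone with a Class A-style outgroup, so the expected
verdicts are: BVMO monophyletic, NMO monophyletic, FMO paraphyletic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .motifs import STANDARD_AA, DegeneratePattern, default_registry
from .msa import GAP, Msa

__all__ = [
    "Placement",
    "SimConfig",
    "DEFAULT_PLACEMENTS",
    "sample_tree",
    "make_root_sequence",
    "evolve_sequences",
    "make_survey",
    "inject_gap_columns",
    "SurveyBundle",
]

_N_AA = len(STANDARD_AA)
_AA_ARR = np.frombuffer(STANDARD_AA.encode(), dtype="S1")


@dataclass(frozen=True)
class Placement:
    """One fingerprint planted at a fixed position of a family's sequence.

    ``start`` is 1-based; ``overrides`` pins selected pattern positions
    (1-based within the motif) to a specific residue at installation time —
    used to give the ancestral second BVMO fingerprint its consensus Thr,
    which then erodes freely because that position is unconstrained.
    """

    pattern_id: str
    start: int
    overrides: dict[int, str] = field(default_factory=dict)


#: Family fingerprint architectures used by the survey generator.  The two
#: Rossmann motifs are common to every Class B family (and the outgroup);
#: family-specific fingerprints sit between them.
DEFAULT_PLACEMENTS: dict[str, tuple[Placement, ...]] = {
    "base": (Placement("rossmann", 10), Placement("rossmann", 140)),
    "BVMO": (
        Placement("bvmo_fp1", 40),
        Placement("bvmo_fp2", 90, overrides={8: "T"}),
    ),
    "FMO": (Placement("fmo_fp", 90),),
    "NMO": (),
    "ClassA": (),
    "background": (),
}


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic survey (deterministic per seed)."""

    seed: int = 0
    n_bvmo: int = 10
    n_fmo: int = 12
    n_nmo: int = 8
    n_outgroup: int = 4
    n_background: int = 16
    seq_length: int = 250
    #: mean of the exponential within-family edge lengths (expected
    #: substitutions per site per edge)
    family_edge_mean: float = 0.06
    family_stem: float = 0.25
    spine_edge: float = 0.12
    outgroup_stem: float = 0.5
    subst_rate: float = 1.0
    clade_structure: str = "nested"  # "nested" | "separate"
    n_gap_columns: int = 0
    placements: dict[str, tuple[Placement, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PLACEMENTS)
    )

    def __post_init__(self) -> None:
        for name in ("n_bvmo", "n_fmo", "n_nmo", "n_outgroup", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.clade_structure not in ("nested", "separate"):
            raise ValueError(f"unknown clade_structure {self.clade_structure!r}")
        if self.clade_structure == "nested" and 0 < self.n_fmo < 3:
            raise ValueError("nested layout needs n_fmo >= 3 (FMO backbone in three blocks)")


# ---------------------------------------------------------------------------
# trees


def _join_random(nodes: list[dendropy.Node], edge_mean: float, rng: np.random.Generator,
                 down_to: int = 1) -> list[dendropy.Node]:
    """Random pairwise joining (Yule topology); child edges ~ Exp(edge_mean)."""
    nodes = list(nodes)
    while len(nodes) > down_to:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            child = nodes[k]
            parent.add_child(child)
            child.edge.length = float(rng.exponential(edge_mean))
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    return nodes


def _leaf(label: str) -> dendropy.Node:
    nd = dendropy.Node()
    nd._pending_label = label
    return nd


def _finalize_tree(root: dendropy.Node) -> dendropy.Tree:
    """Attach a shared taxon namespace to the pending leaf labels."""
    labels = [nd._pending_label for nd in root.leaf_iter()]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    for nd, taxon in zip(root.leaf_iter(), ns):
        nd.taxon = taxon
    tree.is_rooted = True
    return tree


def sample_tree(n_leaves: int, yule_rate: float, seed: int | None = None,
                prefix: str = "T") -> dendropy.Tree:
    """Rooted Yule-topology tree with i.i.d. exponential branch lengths.

    ``yule_rate`` is the rate of the exponential edge-length distribution
    (mean ``1/yule_rate`` substitutions per site per edge).
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = np.random.default_rng(seed)
    leaves = [_leaf(f"{prefix}{i + 1}") for i in range(n_leaves)]
    root = _join_random(leaves, 1.0 / yule_rate, rng)[0]
    return _finalize_tree(root)


def _subtree(labels: list[str], edge_mean: float, rng) -> dendropy.Node:
    if len(labels) == 1:
        return _leaf(labels[0])
    return _join_random([_leaf(l) for l in labels], edge_mean, rng)[0]


def _graft(children: list[tuple[dendropy.Node, float]]) -> dendropy.Node:
    parent = dendropy.Node()
    for child, stem in children:
        parent.add_child(child)
        child.edge.length = stem
    return parent


def _survey_tree(cfg: SimConfig, ids: dict[str, list[str]], rng) -> dendropy.Tree:
    """One tree holding the outgroup and all family clades.

    nested:   (ClassA, (FMO_a, (BVMO, (FMO_b, (NMO, FMO_c)))))
    separate: (ClassA, (BVMO, (NMO, FMO)))
    """
    em = cfg.family_edge_mean

    def fam(labels):
        node = _subtree(labels, em, rng)
        return node

    out = fam(ids["ClassA"])
    bvmo = fam(ids["BVMO"])
    bvmo.install_family = "BVMO"
    nmo = fam(ids["NMO"])
    nmo.install_family = "NMO"

    if cfg.clade_structure == "nested":
        f = ids["FMO"]
        third = max(1, len(f) // 3)
        fa, fb, fc = f[:third], f[third : 2 * third], f[2 * third :]
        parts = []
        for chunk in (fa, fb, fc):
            nd = fam(chunk)
            nd.install_family = "FMO"
            parts.append(nd)
        inner = _graft([(nmo, cfg.family_stem), (parts[2], cfg.spine_edge)])
        mid = _graft([(parts[1], cfg.spine_edge), (inner, cfg.spine_edge)])
        low = _graft([(bvmo, cfg.family_stem), (mid, cfg.spine_edge)])
        ingroup = _graft([(parts[0], cfg.spine_edge), (low, cfg.spine_edge)])
    else:
        fmo = fam(ids["FMO"])
        fmo.install_family = "FMO"
        inner = _graft([(nmo, cfg.family_stem), (fmo, cfg.family_stem)])
        ingroup = _graft([(bvmo, cfg.family_stem), (inner, cfg.spine_edge)])

    root = _graft([(out, cfg.outgroup_stem), (ingroup, cfg.spine_edge)])
    out.install_family = "ClassA"
    return _finalize_tree(root)


# ---------------------------------------------------------------------------
# sequences


def _placement_windows(placements, registry) -> list[tuple[int, int]]:
    """0-based half-open [start, end) windows, validated in order and disjoint."""
    wins = []
    for p in placements:
        pat = registry[p.pattern_id]
        s0 = p.start - 1
        wins.append((s0, s0 + len(pat)))
    for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
        if e1 > s2:
            raise ValueError("placements overlap or are out of order")
    return wins


def _realize(pattern: DegeneratePattern, overrides, rng) -> np.ndarray:
    out = np.empty(len(pattern), dtype=np.int64)
    for k, pos in enumerate(pattern.positions):
        if k + 1 in overrides:
            out[k] = STANDARD_AA.index(overrides[k + 1])
        elif pos is None:
            out[k] = rng.integers(_N_AA)
        else:
            out[k] = STANDARD_AA.index(
                sorted(pos)[rng.integers(len(pos))]
            )
    return out


def _decode(arr: np.ndarray) -> str:
    return _AA_ARR[arr].tobytes().decode()


def _forbidden_occurrence(seq: str, placements, registry, forbid_ids) -> bool:
    """Any occurrence of a forbidden pattern outside the planted windows?"""
    from .motifs import scan_sequence

    wins = _placement_windows(placements, registry) if placements else []
    for pid in forbid_ids:
        for h in scan_sequence(seq, registry[pid]):
            s0, e0 = h.start - 1, h.end  # half-open
            if not any(s0 >= ws and e0 <= we for ws, we in wins):
                return True
    return False


def make_root_sequence(
    family: str,
    length: int,
    placements: tuple[Placement, ...],
    rng: np.random.Generator,
    registry: dict[str, DegeneratePattern] | None = None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Ancestral sequence: i.i.d. background with planted fingerprint realizations.

    Background segments are rejection-resampled until no registered pattern
    occurs outside the planted windows, so classification truth is
    unambiguous by construction.  Returns an integer-encoded sequence.
    """
    registry = registry if registry is not None else default_registry()
    wins = _placement_windows(placements, registry)
    if wins and wins[-1][1] > length:
        raise ValueError("placements do not fit within the sequence length")
    planted = np.full(length, -1, dtype=np.int64)
    for p, (s0, e0) in zip(placements, wins):
        planted[s0:e0] = _realize(registry[p.pattern_id], p.overrides, rng)
    bg_mask = planted < 0
    forbid = list(registry)
    for _ in range(max_tries):
        seq = planted.copy()
        seq[bg_mask] = rng.integers(_N_AA, size=int(bg_mask.sum()))
        if not _forbidden_occurrence(_decode(seq), placements, registry, forbid):
            return seq
    raise RuntimeError(f"could not draw a clean {family} background in {max_tries} tries")


def _constraints_for(placements, registry) -> dict[int, np.ndarray]:
    """0-based site -> allowed residue indices, for constrained motif positions."""
    cons: dict[int, np.ndarray] = {}
    for p in placements:
        pat = registry[p.pattern_id]
        for k, pos in enumerate(pat.positions):
            if pos is not None:
                cons[p.start - 1 + k] = np.array(
                    sorted(STANDARD_AA.index(c) for c in pos), dtype=np.int64
                )
    return cons


def _mutate(seq: np.ndarray, branch_length: float, rate: float,
            constraints: dict[int, np.ndarray], rng) -> np.ndarray:
    p = 1.0 - np.exp(-rate * branch_length)
    out = seq.copy()
    for site in np.flatnonzero(rng.random(seq.size) < p):
        allowed = constraints.get(site)
        if allowed is None:
            out[site] = (out[site] + rng.integers(1, _N_AA)) % _N_AA
        else:
            others = allowed[allowed != out[site]]
            if others.size:
                out[site] = others[rng.integers(others.size)]
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    root_seq: np.ndarray | str,
    rate: float,
    constraints: dict[int, np.ndarray] | None = None,
    seed: int | None = None,
) -> Msa:
    """Evolve a root sequence along a tree; returns the true (ungapped) alignment.

    Constrained sites substitute only within their allowed sets; there are
    no indels, so rows are the leaf states of the site matrix, in leaf order.
    """
    if rate < 0:
        raise ValueError("substitution rate must be >= 0")
    if isinstance(root_seq, str):
        root_seq = np.array([STANDARD_AA.index(c) for c in root_seq], dtype=np.int64)
    constraints = constraints or {}
    for site, allowed in constraints.items():
        if root_seq[site] not in allowed:
            raise ValueError(f"root residue at site {site} outside its constraint set")
    rng = np.random.default_rng(seed)
    seqs = _evolve_walk(tree.seed_node, root_seq, rate, constraints, rng, installs=None)
    return Msa.from_records([(lf.taxon.label, _decode(seqs[lf])) for lf in
                             tree.seed_node.leaf_iter()])


def _evolve_walk(root, root_seq, rate, base_constraints, rng, installs):
    """Iterative preorder walk; ``installs`` maps family name ->
    (placements, registry) applied at nodes carrying ``install_family``."""
    seqs: dict[dendropy.Node, np.ndarray] = {}
    stack = [(root, root_seq, base_constraints)]
    while stack:
        node, seq, cons = stack.pop()
        fam = getattr(node, "install_family", None)
        if installs is not None and fam is not None and fam in installs:
            placements, registry = installs[fam]
            seq = seq.copy()
            wins = _placement_windows(placements, registry)
            for p, (s0, e0) in zip(placements, wins):
                seq[s0:e0] = _realize(registry[p.pattern_id], p.overrides, rng)
            cons = {**cons, **_constraints_for(placements, registry)}
        if node.is_leaf():
            seqs[node] = seq
        for child in node.child_nodes():
            stack.append((child, _mutate(seq, child.edge.length or 0.0, rate, cons, rng),
                          cons))
    return seqs


# ---------------------------------------------------------------------------
# surveys


@dataclass(frozen=True)
class SurveyBundle:
    """All artifacts of one synthetic survey, cross-consistent by id."""

    config: SimConfig
    proteome: dict[str, str]
    truth: pd.DataFrame  # seq_id, family
    tree: dendropy.Tree
    alignment: Msa  # true alignment over tree leaves (no backgrounds)
    contamination: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "proteome.fasta", "w") as fh:
            for sid, seq in self.proteome.items():
                fh.write(f">{sid}\n{seq}\n")
        self.truth.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
        with open(outdir / "true_tree.nwk", "w") as fh:
            fh.write(self.tree.as_string(schema="newick"))
        self.alignment.to_fasta(outdir / "true_alignment.fasta")
        self.contamination.to_csv(outdir / "contamination.tsv", sep="\t", index=False)


def _contamination_fixture(rng) -> pd.DataFrame:
    """Three screened contigs: bacterially contaminated, consistent, ambiguous."""
    from .contamination import ContigAnnotation, GeneContext, contigs_to_table

    def contig(cid, host, flank_labels):
        genes = [GeneContext(f"{cid}_g{i}", lab) for i, lab in enumerate(flank_labels)]
        genes.insert(len(genes) // 2, GeneContext(f"{cid}_bvmo", "unassigned", focal=True))
        return ContigAnnotation(cid, host, tuple(genes))

    return contigs_to_table(
        [
            contig("contig_suspect", "Eukaryota", ["Bacteria"] * 4),
            contig("contig_consistent", "Eukaryota",
                   ["Eukaryota", "Eukaryota", "Bacteria", "Eukaryota"]),
            contig("contig_sparse", "Eukaryota", ["unassigned", "Bacteria", "unassigned"]),
        ]
    )


def make_survey(config: SimConfig) -> SurveyBundle:
    """Generate one full synthetic survey, byte-deterministic per seed."""
    registry = default_registry()
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_root, rng_evolve, rng_bg, rng_cont = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    ids = {
        "BVMO": [f"BVMO{i + 1:02d}" for i in range(config.n_bvmo)],
        "FMO": [f"FMO{i + 1:02d}" for i in range(config.n_fmo)],
        "NMO": [f"NMO{i + 1:02d}" for i in range(config.n_nmo)],
        "ClassA": [f"ClassA{i + 1:02d}" for i in range(config.n_outgroup)],
    }
    bg_ids = [f"BG{i + 1:02d}" for i in range(config.n_background)]

    tree = _survey_tree(config, ids, rng_tree)

    base = config.placements["base"]
    root_seq = make_root_sequence("ancestor", config.seq_length, base, rng_root,
                                  registry=registry)
    installs = {
        fam: (config.placements[fam], registry)
        for fam in ("BVMO", "FMO", "NMO", "ClassA")
    }
    seqs = _evolve_walk(tree.seed_node, root_seq, config.subst_rate,
                        _constraints_for(base, registry), rng_evolve, installs)
    alignment = Msa.from_records(
        [(lf.taxon.label, _decode(seqs[lf])) for lf in tree.seed_node.leaf_iter()]
    )

    proteome = {sid: alignment.ungapped(sid) for sid in alignment.ids}
    for bid in bg_ids:
        proteome[bid] = _decode(
            make_root_sequence("background", config.seq_length, (), rng_bg,
                               registry=registry)
        )

    fam_of = {sid: fam for fam, members in ids.items() for sid in members}
    fam_of.update({bid: "background" for bid in bg_ids})
    truth = pd.DataFrame(
        {"seq_id": list(proteome), "family": [fam_of[s] for s in proteome]}
    )

    bundle = SurveyBundle(
        config=config,
        proteome=proteome,
        truth=truth,
        tree=tree,
        alignment=alignment,
        contamination=_contamination_fixture(rng_cont),
    )
    if config.n_gap_columns > 0:
        gapped = inject_gap_columns(alignment, config.n_gap_columns,
                                    np.random.default_rng(ss.spawn(1)[0]))
        bundle = replace(bundle, alignment=gapped)
    return bundle


def inject_gap_columns(msa: Msa, n_columns: int, rng: np.random.Generator) -> Msa:
    """Insert ``n_columns`` new columns, each gapped in a random non-empty
    proper subset of rows — exercises gap-column editing and pairwise-deletion
    identity without an indel model."""
    arr = msa.to_array()
    n, L = arr.shape
    positions = np.sort(rng.integers(0, L + 1, size=n_columns))
    cols = []
    for _ in range(n_columns):
        k = int(rng.integers(1, n))  # 1..n-1 gaps
        gap_rows = rng.choice(n, size=k, replace=False)
        col = _AA_ARR[rng.integers(_N_AA, size=n)]
        col[gap_rows] = GAP.encode()
        cols.append(col)
    out = []
    for r in range(n):
        row = list(msa.rows[r])
        for pos, col in sorted(zip(positions, cols), key=lambda t: -t[0]):
            row.insert(int(pos), col[r].decode())
        out.append("".join(row))
    return Msa(msa.ids, tuple(out))
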