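"""Taxonomy-concordance screen for assembly contamination.

A eukaryotic draft genome occasionally carries contigs of bacterial origin
introduced during sequencing or assembly; a monooxygenase ORF found on such
a contig is a contamination artifact, not a host gene.  The screen inspects
the genes flanking the focal ORF on each contig: if enough of them have
best-hit taxonomy assignments and a large fraction disagree with the host's
superkingdom, the contig is flagged.  Taxonomy labels are precomputed inputs
(e.g. from reciprocal translated-BLAST searches); the screen itself is pure
bookkeeping and depends only on the multiset of labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneContext", "ContigAnnotation", "screen_contigs",
           "contigs_from_table", "contigs_to_table"]

SUPERKINGDOMS = {"Bacteria", "Archaea", "Eukaryota", "unassigned"}

VERDICT_SUSPECT = "suspect-contamination"
VERDICT_CONSISTENT = "consistent"
VERDICT_INSUFFICIENT = "insufficient-context"


@dataclass(frozen=True)
class GeneContext:
    gene_id: str
    label: str  # best-hit superkingdom, or "unassigned"
    focal: bool = False  # the monooxygenase-like ORF under scrutiny


@dataclass(frozen=True)
class ContigAnnotation:
    contig_id: str
    host_superkingdom: str
    genes: tuple[GeneContext, ...]

    def __post_init__(self) -> None:
        if self.host_superkingdom not in SUPERKINGDOMS - {"unassigned"}:
            raise ValueError(f"invalid host superkingdom {self.host_superkingdom!r}")
        for g in self.genes:
            if g.label not in SUPERKINGDOMS:
                raise ValueError(f"invalid label {g.label!r} on gene {g.gene_id!r}")
        n_focal = sum(g.focal for g in self.genes)
        if n_focal != 1:
            raise ValueError(
                f"contig {self.contig_id!r} has {n_focal} focal genes, expected exactly 1"
            )


def screen_contigs(
    contigs: list[ContigAnnotation],
    min_flank: int = 2,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-contig contamination verdicts.

    A contig is ``suspect-contamination`` when at least ``min_flank``
    non-focal genes carry a superkingdom assignment and the fraction
    assigned to a superkingdom other than the host's is >= ``threshold``;
    ``consistent`` when that fraction is below the threshold; and
    ``insufficient-context`` with fewer than ``min_flank`` labelled flanking
    genes.  ``unassigned`` genes count in neither numerator nor denominator.
    """
    rows = []
    for contig in contigs:
        labelled = [g for g in contig.genes if not g.focal and g.label != "unassigned"]
        n = len(labelled)
        if n < min_flank:
            verdict, frac = VERDICT_INSUFFICIENT, None
        else:
            discordant = sum(1 for g in labelled if g.label != contig.host_superkingdom)
            frac = discordant / n
            verdict = VERDICT_SUSPECT if frac >= threshold else VERDICT_CONSISTENT
        rows.append(
            {
                "contig_id": contig.contig_id,
                "host_superkingdom": contig.host_superkingdom,
                "n_labelled_flanking": n,
                "discordant_fraction": frac,
                "verdict": verdict,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["contig_id", "host_superkingdom", "n_labelled_flanking",
                 "discordant_fraction", "verdict"],
    )
    # keep undefined fractions as None (not NaN) so reports serialize cleanly
    df["discordant_fraction"] = df["discordant_fraction"].astype(object).where(
        df["discordant_fraction"].notna(), None)
    return df


def contigs_from_table(df: pd.DataFrame) -> list[ContigAnnotation]:
    """Build contig annotations from a long table
    (contig_id, host_superkingdom, gene_id, order_index, label, focal)."""
    contigs = []
    for cid, grp in df.groupby("contig_id", sort=False):
        grp = grp.sort_values("order_index")
        genes = tuple(
            GeneContext(str(r.gene_id), str(r.label), bool(r.focal))
            for r in grp.itertuples()
        )
        contigs.append(ContigAnnotation(str(cid), str(grp.iloc[0].host_superkingdom), genes))
    return contigs


def contigs_to_table(contigs: list[ContigAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": c.contig_id,
            "host_superkingdom": c.host_superkingdom,
            "gene_id": g.gene_id,
            "order_index": i,
            "label": g.label,
            "focal": g.focal,
        }
        for c in contigs
        for i, g in enumerate(c.genes)
    ]
    return pd.DataFrame(rows)
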