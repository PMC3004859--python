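"""Dense-overlapping-regulon (DOR) assembly and the effector-gene signature.

Candidate TF→gene links come from two provenances: a promoter binding-site
scan and literature curation.  Candidates are combined, the TF list is
intersected with the set of array-modulated TFs (activated or suppressed),
and the restriction of the candidate edges to that shortlist forms the DOR —
a bipartite module in which a shared set of TFs combinatorially regulates a
shared set of early-induced genes.

The effector signature is the set difference between the early genes induced
in the arrested (immature-type) cells and those also induced in mature B
cells: genes shared with the mature response are unlikely to drive the
G1-arrest phenotype and are subtracted out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .tf_array import TFCallTable

logger = logging.getLogger(__name__)

PROVENANCE_SCAN = "scan"
PROVENANCE_LITERATURE = "literature"


def normalize_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Case-normalize a gene/TF symbol, resolving known aliases
    (e.g. TNFa→TNF) first."""
    s = symbol.strip()
    if aliases:
        folded = {k.upper(): v for k, v in aliases.items()}
        s = folded.get(s.upper(), s)
    return s.upper()


@dataclass
class RegulatoryModule:
    """Directed bipartite TF→gene module with per-edge provenance."""

    tf_set: set[str]
    gene_set: set[str]
    edges: dict[tuple[str, str], set[str]]  # (tf, gene) -> provenance set
    orphan_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for tf, gene in self.edges:
            if tf not in self.tf_set or gene not in self.gene_set:
                raise ValueError(f"edge ({tf},{gene}) endpoint outside module sets")
        if self.tf_set & self.gene_set:
            raise ValueError("module must be bipartite: TF and gene sets overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tf": tf, "gene": gene, "provenance": "|".join(sorted(prov))}
            for (tf, gene), prov in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["tf", "gene", "provenance"])


def _validate_candidates(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "tf", "provenance"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    return table


def combine_candidates(
    scan: pd.DataFrame, literature: pd.DataFrame,
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Union of the scan and literature candidate tables.

    Returns a deduplicated table (gene, tf, provenance) where a link found by
    both approaches appears once per provenance; symbols are case-normalized
    through the alias table.
    """
    frames = [f for f in (scan, literature) if f is not None and len(f)]
    if not frames:
        return pd.DataFrame(columns=["gene", "tf", "provenance"])
    combined = pd.concat([_validate_candidates(f) for f in frames], ignore_index=True)
    combined = combined.assign(
        gene=combined.gene.map(lambda s: normalize_symbol(s, aliases)),
        tf=combined.tf.map(lambda s: normalize_symbol(s, aliases)),
    )
    combined = combined.drop_duplicates(["gene", "tf", "provenance"])
    return combined.sort_values(["gene", "tf", "provenance"]).reset_index(drop=True)


def shortlist_modulated(
    candidates: pd.DataFrame, calls: TFCallTable,
    aliases: dict[str, str] | None = None,
) -> set[str]:
    """Candidate TFs whose array status is activated or suppressed.

    Candidate TFs absent from the call table are treated as unaffected with
    a warning, never silently dropped.
    """
    candidate_tfs = {normalize_symbol(t, aliases) for t in candidates.tf}
    modulated = {normalize_symbol(t, aliases) for t in calls.modulated}
    covered = {normalize_symbol(c.tf_id, aliases) for c in calls.calls}
    uncovered = candidate_tfs - covered
    if uncovered:
        logger.warning(
            "candidate TFs absent from the call table, treated as unaffected: %s",
            sorted(uncovered),
        )
    return candidate_tfs & modulated


def build_dor(candidates: pd.DataFrame, shortlist: set[str]) -> RegulatoryModule:
    """Restrict the candidate TF→gene edges to the shortlisted TFs.

    Genes losing every regulator stay in the gene set, flagged as orphans.
    """
    candidates = _validate_candidates(candidates)
    unknown = set(shortlist) - set(candidates.tf)
    if unknown:
        raise ValueError(f"shortlist TFs absent from candidate table: {sorted(unknown)}")
    genes = set(candidates.gene)
    edges: dict[tuple[str, str], set[str]] = {}
    for row in candidates.itertuples(index=False):
        if row.tf in shortlist:
            edges.setdefault((row.tf, row.gene), set()).add(row.provenance)
    regulated = {gene for _, gene in edges}
    return RegulatoryModule(
        tf_set=set(shortlist),
        gene_set=genes,
        edges=edges,
        orphan_genes=genes - regulated,
    )


def effector_signature(
    induced_focus: set[str],
    induced_reference: set[str],
    aliases: dict[str, str] | None = None,
) -> set[str]:
    """Genes induced in the focus cells but not in the reference cells.

    Both sets are case-normalized through the alias table before the
    subtraction, so e.g. TNF and TNFa compare equal.
    """
    focus = {normalize_symbol(g, aliases) for g in induced_focus}
    reference = {normalize_symbol(g, aliases) for g in induced_reference}
    return focus - reference


def read_gene_list(path) -> set[str]:
    """One symbol per line; blank lines and #-comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
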