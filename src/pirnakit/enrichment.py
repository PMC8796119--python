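"""Observed/expected enrichment of a target set in gene-expression categories.

For a target set of size ``n`` and a category of size ``m`` drawn from a
universe of ``N`` protein-coding genes, the expected overlap under random
placement is ``n * m / N`` and the enrichment factor is observed/expected.
The default universe size is 20,447 C. elegans protein-coding genes.
"""
from __future__ import annotations

from dataclasses import dataclass

TOTAL_PROTEIN_CODING_GENES = 20_447


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    enrichment: float | None
    n_targets: int
    category_size: int
    total_genes: int


def enrichment_factor(
    target_set,
    category_set,
    total_genes: int = TOTAL_PROTEIN_CODING_GENES,
    category: str = "",
) -> EnrichmentResult:
    """Observed/expected enrichment of ``target_set`` within ``category_set``.

    ``enrichment`` is None when the expectation is zero (empty category or
    empty target set).
    """
    targets = set(target_set)
    cat = set(category_set)
    if total_genes <= 0:
        raise ValueError("total_genes must be > 0")
    if total_genes < max(len(targets), len(cat)):
        raise ValueError("total_genes smaller than an input set")
    observed = len(targets & cat)
    expected = len(targets) * len(cat) / total_genes
    enrichment = observed / expected if expected > 0 else None
    return EnrichmentResult(
        category=category,
        observed=observed,
        expected=expected,
        enrichment=enrichment,
        n_targets=len(targets),
        category_size=len(cat),
        total_genes=total_genes,
    )
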