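"""Shared fixtures: one default synthetic family per test session."""

from __future__ import annotations

import pytest

from zmgras.census import (
    build_census,
    collapse_to_genes,
    filter_family_hits,
    splice_form_counts,
)
from zmgras.synthetic import (
    SyntheticFamilySpec,
    generate_expression,
    generate_family,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def family():
    """The default planted-truth synthetic family (fixed seed)."""
    return generate_family(SyntheticFamilySpec(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def expression_bundle(family):
    """(expression matrix, Ct table) for the default family; also fills the
    truth's expression fields."""
    expr, ct = generate_expression(family.spec, family.truth)
    return expr, ct


@pytest.fixture(scope="session")
def family_census(family):
    """Census entries plus locus->representative map for the default family."""
    members = filter_family_hits(family.domain_hits)
    genes = collapse_to_genes(members, family.proteins + family.decoys)
    splice = splice_form_counts(members, family.proteins + family.decoys)
    entries = build_census(
        genes, family.gene_models, naming_prefix="SYN", splice_forms=splice
    )
    return entries, genes
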