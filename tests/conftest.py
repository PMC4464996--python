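"""Shared fixtures: a folding backend with a warm cache, a reduced synthetic
corpus for pipeline-level tests, and cutoff sets derived from synthetic
reference hairpin populations."""

from collections import defaultdict

import pytest

from mirsig import descriptors, ssr, synthetic
from mirsig.folding import BuiltinBackend
from mirsig.seqio import parse_mirna_name


@pytest.fixture(scope="session")
def backend():
    return BuiltinBackend()


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus (6 families, 4 planted ESTs, 20 decoys)."""
    return synthetic.make_corpus(
        n_families=6, n_planted=4, n_decoys=20, seed=42
    )


@pytest.fixture(scope="session")
def small_cutoffs(backend):
    """Cutoffs from a 150-hairpin synthetic reference population."""
    ref = synthetic.make_reference_set(150, seed=3)
    table = [descriptors.compute_descriptors(r.seq, backend.fold(r.seq)) for r in ref]
    return descriptors.derive_cutoffs(table)


@pytest.fixture(scope="session")
def small_catalog(small_corpus):
    groups = defaultdict(list)
    for rec in small_corpus.known_precursors:
        groups[parse_mirna_name(rec.id).family].append(rec)
    return ssr.build_catalog(dict(groups))
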