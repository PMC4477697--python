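"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from protasm.psm_io import BipartiteMap


def brute_force_fdr(scores, is_decoy, threshold):
    """Direct recount of the decoy-doubling estimator."""
    t = sum(1 for s, d in zip(scores, is_decoy) if s >= threshold and not d)
    d = sum(1 for s, dd in zip(scores, is_decoy) if s >= threshold and dd)
    return min(1.0, 2.0 * d / (t + d))


def brute_force_min_cover(pep_to_prot: dict[str, frozenset], peptides) -> int:
    """Exhaustive minimum set cover size over indiscernible-protein clusters."""
    inv: dict[str, set] = {}
    for pep, owners in pep_to_prot.items():
        for acc in owners:
            inv.setdefault(acc, set()).add(pep)
    clusters: dict[frozenset, list] = {}
    for acc, peps in inv.items():
        clusters.setdefault(frozenset(peps), []).append(acc)
    keys = list(clusters)
    target = set(peptides)
    for r in range(1, len(keys) + 1):
        for combo in itertools.combinations(keys, r):
            if set().union(*combo) >= target:
                return r
    raise AssertionError("no cover exists")


def protein_like_instance(rng: np.random.Generator, max_proteins: int = 12):
    """Random bipartite instance shaped like protein-inference evidence:
    proteins carry 0-4 unique observed peptides plus planted shared peptides."""
    n_prot = int(rng.integers(3, max_proteins + 1))
    accs = [f"P{i:02d}" for i in range(n_prot)]
    pep_to_prot: dict[str, set] = {}
    pid = 0
    for acc in accs:
        for _ in range(int(rng.integers(0, 5))):
            pep_to_prot[f"PEP{pid:03d}"] = {acc}
            pid += 1
    for _ in range(int(rng.integers(1, n_prot))):
        k = int(rng.integers(2, min(4, n_prot) + 1))
        owners = set(rng.choice(accs, size=k, replace=False))
        pep_to_prot[f"PEP{pid:03d}"] = owners
        pid += 1
    p2p = {p: frozenset(o) for p, o in pep_to_prot.items()}
    bmap = BipartiteMap(p2p, {a: a for a in accs}, {a: 100 for a in accs})
    return bmap, p2p


@pytest.fixture
def tiny_bmap():
    """Hand-built map: A and B indiscernible on {p1, p2}; C adds p3; D is a
    one-peptide protein; X decoy with its own peptides."""
    p2p = {
        "PEPTIDEONEK": frozenset({"A", "B"}),
        "PEPTIDETWOK": frozenset({"A", "B"}),
        "PEPTIDETHREEK": frozenset({"C"}),
        "PEPTIDEFOURK": frozenset({"C"}),
        "PEPTIDEFIVEK": frozenset({"D"}),
        "KENODITPEP": frozenset({"XXX_A"}),
        "KOWTEDITPEP": frozenset({"XXX_A"}),
    }
    genes = {"A": "gA", "B": "gB", "C": "gC", "D": "gD", "XXX_A": "XXX_gA"}
    lengths = {"A": 300, "B": 250, "C": 400, "D": 120, "XXX_A": 300}
    return BipartiteMap(p2p, genes, lengths)
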