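"""Shared fixtures: a small simulated mobilome dataset loaded once per session."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pytest

from mobatp import io as mio
from mobatp.simulate import SimConfig, simulate_dataset


@dataclass
class SimData:
    paths: object
    truth: object
    proteins: dict
    genes: list
    genes_dedup: list  # duplicate gene calls removed (post-dedup gene set)
    domain_hits: list
    homology: list
    taxonomy: list

    def genes_by_contig(self, dedup: bool = False) -> dict:
        out: dict = {}
        for g in (self.genes_dedup if dedup else self.genes):
            out.setdefault(g.contig_id, []).append(g)
        return out


def permutation_agreement(labels, truth) -> float:
    """Best label agreement over all bijections of predicted onto true names."""
    pred_names = sorted(set(labels))
    best = 0.0
    for perm in itertools.permutations(sorted(set(truth))):
        mapping = dict(zip(pred_names, perm))
        acc = np.mean([mapping[p] == t for p, t in zip(labels, truth)])
        best = max(best, float(acc))
    return best


def _load(paths, truth) -> SimData:
    proteins = dict(mio.read_protein_fasta(paths.proteins_fasta))
    genes = mio.read_gene_table(paths.gene_table, proteins=proteins)
    return SimData(
        paths=paths,
        truth=truth,
        proteins=proteins,
        genes=genes,
        genes_dedup=[g for g in genes if g.gene_id not in truth.duplicates],
        domain_hits=mio.read_domain_hits(paths.domain_table),
        homology=mio.read_homology_table(paths.homology_table),
        taxonomy=mio.read_taxonomy_table(paths.taxonomy_table),
    )


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory) -> SimData:
    """A dense small dataset: 12 genomes, half of ATPase proteins composite."""
    cfg = SimConfig(
        n_genomes=12,
        length_range_kbp=(104.0, 735.0),
        composite_fraction=0.5,
        n_duplicate_candidates=20,
        seed=3,
    )
    paths, truth = simulate_dataset(cfg, tmp_path_factory.mktemp("sim_small"))
    return _load(paths, truth)


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory) -> SimData:
    """Default study conditions at reduced genome count (for context tests)."""
    cfg = SimConfig(n_genomes=40, seed=0)
    paths, truth = simulate_dataset(cfg, tmp_path_factory.mktemp("sim_default"))
    return _load(paths, truth)
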