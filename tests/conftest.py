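"""Shared fixtures: programmatic input tables and the receptor-mutation
catalogue used by the spectrum tests."""

from __future__ import annotations

import pandas as pd
import pytest

from phage_evo.mutation_analysis import VariantRecord


@pytest.fixture
def growth_csv(tmp_path):
    """Write a long-format growth table and return its path."""

    def _write(rows, name="plate.csv", columns=None):
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    return _write


def _rec(gene, mutation_type, nt, aa=None, sample="s", indel=None):
    return VariantRecord(
        sample_id=sample, gene=gene, mutation_type=mutation_type,
        nt_change=nt, aa_change=aa, indel_len=indel,
    )


@pytest.fixture(scope="session")
def receptor_mutation_catalogue():
    """The catalogue of receptor-associated resistance mutations observed
    across the sequenced resistant clones: 14 distinct LPS-pathway genes
    (rfb cluster, rfc, rfa cluster, rfaH, pgm, galE) and btuB."""
    return [
        _rec("rfbD", "frameshift", "1 bp del.", indel=1),
        _rec("rfbC", "nonsense", "294:G>A", "W98*"),
        _rec("rfbV", "nonsense", "406:C>T", "R136*"),
        _rec("rfbU", "large_indel", "824 bp del.", indel=824),
        _rec("rfbP", "frameshift", "1 bp del.", indel=1),
        _rec("rfbP", "missense", "1271:G>A", "G424D"),
        _rec("rfc", "large_indel", "2383 bp del.", indel=2383),
        _rec("rfaF", "frameshift", "1 bp ins.", indel=1),
        _rec("rfaJ", "nonsense", "7:C>A", "S3*"),
        _rec("rfaJ", "nonsense", "571:G>T", "E191*"),
        _rec("rfaJ", "missense", "10:T>C", "F4L"),
        _rec("rfaJ", "missense", "593:C>T", "A198V"),
        _rec("rfaJ", "missense", "686:T>C", "L229P"),
        _rec("rfaJ", "missense", "824:C>A", "A275E"),
        _rec("rfaJ", "missense", "648:T>A", "D216E"),
        _rec("rfaJ", "missense", "787:C>A", "H263N"),
        _rec("rfaJ", "frameshift", "1 bp ins.", indel=1),
        _rec("rfaI", "nonsense", "808:G>T", "G270*"),
        _rec("rfaI", "nonsense", "824:G>A", "W275*"),
        _rec("rfaI", "frameshift", "1 bp del.", indel=1),
        _rec("rfaP", "missense", "103:C>A", "R35S"),
        _rec("rfaG", "frameshift", "1 bp del.", indel=1),
        _rec("rfaH", "nonsense", "11:G>A", "W4*"),
        _rec("rfaH", "frameshift", "1 bp del.", indel=1),
        _rec("pgm", "frameshift", "1 bp del.", indel=1),
        _rec("pgm", "large_indel", "78 bp del.", indel=78),
        _rec("galE", "nonsense", "977:G>A", "W326*"),
        _rec("btuB", "frameshift", "1 bp del.", indel=1),
        _rec("btuB", "missense", "1825:T>C", "S609P"),
    ]
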