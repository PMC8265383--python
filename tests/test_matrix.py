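"""Band-matrix container, file dialects, duplicates and private bands."""

import tempfile
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bandpop.exceptions import ParseError, ValidationError
from bandpop.io import (read_genalex_binary, write_genalex_binary,
                        read_tsv, write_tsv)
from bandpop.matrix import (BandMatrix, band_frequency, band_frequencies,
                            find_duplicates, private_bands)

from conftest import make_matrix, random_matrix


# ---- container invariants -------------------------------------------------

def test_rejects_non_binary_values():
    with pytest.raises(ValidationError, match="non-binary"):
        make_matrix([[0, 2], [1, 0]], ["a", "b"])


def test_rejects_empty_matrix():
    with pytest.raises(ValidationError, match="empty"):
        BandMatrix([], [], np.empty((0, 0)), {})


def test_rejects_duplicate_accessions():
    with pytest.raises(ValidationError, match="duplicate accession"):
        BandMatrix(["a", "a"], ["L1"], [[0], [1]], {"a": "p"})


def test_duplicate_rows_are_allowed():
    m = make_matrix([[1, 0], [1, 0]], ["p", "p"])
    assert m.n_individuals == 2


def test_subset_preserves_population_order(small_matrix):
    sub = small_matrix.subset(["popB"])
    assert sub.populations == ["popB"]
    assert sub.n_individuals == 2
    with pytest.raises(KeyError):
        small_matrix.subset(["nope"])


# ---- GenAlEx dialect ------------------------------------------------------

def test_genalex_roundtrip_small_fixture(small_matrix, tmp_path):
    path = tmp_path / "m.csv"
    write_genalex_binary(small_matrix, path)
    back = read_genalex_binary(path)
    assert back == small_matrix
    layout = back.layout()
    assert layout.populations == ("popA", "popB")
    assert layout.sizes == (2, 2)


@settings(max_examples=25, derandomize=True)
@given(st.integers(2, 12), st.integers(1, 15), st.integers(1, 3),
       st.integers(0, 2 ** 31 - 1))
def test_roundtrip_identity_both_dialects(n, m, n_pops, seed):
    rng = np.random.default_rng(seed)
    mat = random_matrix(rng, n, m, n_pops=min(n_pops, n))
    with tempfile.TemporaryDirectory() as d:
        p1, p2 = Path(d) / "a.csv", Path(d) / "b.tsv"
        write_genalex_binary(mat, p1)
        write_tsv(mat, p2)
        for back in (read_genalex_binary(p1), read_tsv(p2)):
            assert back.accession_ids == mat.accession_ids
            assert back.locus_ids == mat.locus_ids
            assert np.array_equal(back.values, mat.values)
            assert back.pop_of == mat.pop_of


def test_tsv_preserves_taxon_column(small_matrix, tmp_path):
    path = tmp_path / "m.tsv"
    write_tsv(small_matrix, path)
    back = read_tsv(path)
    assert back.taxon_of == {"popA": "cultivated", "popB": "wild"}


def _write(tmp_path, lines):
    p = tmp_path / "bad.csv"
    p.write_text("\n".join(lines) + "\n")
    return p


def test_genalex_non_binary_cell_names_row(tmp_path):
    p = _write(tmp_path, [
        "3,4,2,2,2",
        "t,,,popA,popB",
        "Accession,Pop,L1,L2,L3",
        "a1,popA,1,0,1",
        "a2,popA,0,2,1",   # file row 5
        "b1,popB,0,0,0",
        "b2,popB,1,1,1",
    ])
    with pytest.raises(ParseError, match="row 5") as exc:
        read_genalex_binary(p)
    assert exc.value.row == 5


def test_genalex_header_body_count_mismatch(tmp_path):
    p = _write(tmp_path, [
        "2,3,2,2,1",
        "t,,,popA,popB",
        "Accession,Pop,L1,L2",
        "a1,popA,1,0",
        "a2,popB,0,1",      # popA declared 2 but has 1
        "a3,popB,0,1",
    ])
    with pytest.raises(ParseError, match="size mismatch"):
        read_genalex_binary(p)


def test_genalex_duplicate_accession(tmp_path):
    p = _write(tmp_path, [
        "1,2,1,2",
        "t,,,popA",
        "Accession,Pop,L1",
        "a1,popA,1",
        "a1,popA,0",
    ])
    with pytest.raises(ParseError, match="duplicate accession"):
        read_genalex_binary(p)


def test_genalex_malformed_header(tmp_path):
    p = _write(tmp_path, ["x,y", "a", "b", "c"])
    with pytest.raises(ParseError, match="malformed header"):
        read_genalex_binary(p)


def test_missing_cell_strict_vs_drop(tmp_path):
    p = _write(tmp_path, [
        "2,2,1,2",
        "t,,,popA",
        "Accession,Pop,L1,L2",
        "a1,popA,1,",
        "a2,popA,0,1",
    ])
    with pytest.raises(ParseError, match="missing band score"):
        read_genalex_binary(p)
    m = read_genalex_binary(p, on_missing="drop-locus")
    assert m.locus_ids == ["L1"]


def test_write_refuses_zero_loci():
    # zero-locus matrices are rejected at construction already
    with pytest.raises(ValidationError):
        BandMatrix(["a"], [], np.empty((1, 0)), {"a": "p"})


# ---- duplicates -----------------------------------------------------------

def test_find_duplicates_identity_and_triple():
    m = make_matrix([[1, 0], [0, 1], [1, 0]], ["p", "p", "p"])
    assert find_duplicates(m) == [["S1", "S3"]]
    m2 = make_matrix([[1, 0], [1, 0], [1, 0]], ["p", "p", "p"])
    assert find_duplicates(m2) == [["S1", "S2", "S3"]]
    m3 = make_matrix([[1, 0], [0, 1]], ["p", "p"])
    assert find_duplicates(m3) == []


def test_find_duplicates_matches_all_pairs_oracle(rng):
    for _ in range(10):
        m = random_matrix(rng, 10, 4)  # few loci: collisions likely
        # oracle: transitive closure of all-pairs equality
        n = m.n_individuals
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.array_equal(m.values[i], m.values[j]):
                    parent[find(j)] = find(i)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(m.accession_ids[i])
        expected = [g for g in groups.values() if len(g) >= 2]
        assert sorted(map(tuple, find_duplicates(m))) == \
            sorted(map(tuple, expected))


# ---- band frequencies -----------------------------------------------------

def test_band_frequency_basic():
    m = make_matrix([[1]] * 6 + [[0]] * 2, ["p"] * 8)
    assert band_frequency(m, "p", "L001") == 0.75
    z = make_matrix([[0]] * 4, ["p"] * 4)
    assert band_frequency(z, "p", "L001") == 0.0
    with pytest.raises(KeyError):
        band_frequency(m, "nope", "L001")
    with pytest.raises(KeyError):
        band_frequency(m, "p", "L999")


def test_band_frequency_matches_counting_oracle_and_conserves(rng):
    m = random_matrix(rng, 12, 20, n_pops=3)
    for pop in m.populations:
        idx = m.population_indices(pop)
        n = len(idx)
        freqs = band_frequencies(m, pop)
        for j, locus in enumerate(m.locus_ids):
            count = sum(int(m.values[i, j]) for i in idx)
            assert band_frequency(m, pop, locus) == pytest.approx(count / n)
        # conservation: sum over loci of f * N = total band count in block
        assert freqs.sum() * n == pytest.approx(m.values[idx].sum())


# ---- private bands --------------------------------------------------------

def test_private_bands_definitions():
    # L1 in all pops; L2 only in popA (partial); L3 fixed in popB only
    m = make_matrix(
        [[1, 1, 0], [1, 0, 0], [1, 0, 1], [1, 0, 1], [1, 0, 0], [1, 0, 0]],
        ["popA", "popA", "popB", "popB", "popC", "popC"])
    res = private_bands(m)
    assert res.by_population == {"popA": ["L002"], "popB": ["L003"],
                                 "popC": []}
    fixed = private_bands(m, definition="fixed")
    assert fixed.by_population == {"popA": [], "popB": ["L003"], "popC": []}
    with pytest.raises(KeyError):
        private_bands(m, scope=["popA", "nope"])


def test_private_bands_matches_exhaustive_scan(rng):
    m = random_matrix(rng, 9, 30, n_pops=3)
    res = private_bands(m)
    for j, locus in enumerate(m.locus_ids):
        present = [p for p in m.populations
                   if m.values[m.population_indices(p), j].any()]
        for p in m.populations:
            should = (present == [p])
            assert (locus in res.by_population[p]) == should


def test_private_bands_per_primer_tally(small_matrix):
    res = private_bands(small_matrix)
    assert res.per_primer is not None
    assert sum(res.per_primer.values()) == res.total
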