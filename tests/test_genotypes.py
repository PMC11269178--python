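"""Site-matrix construction and the pseudo-haploid filtering pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleoclock import genotypes as gt
from tests.conftest import build_matrix


@pytest.fixture
def mixed_matrix():
    """8 sites mixing transversions/transitions, adjacency and missingness."""
    calls = np.array([
        [0, 1, -1, 0, 1, 0, 1, 0],
        [1, -1, 0, 1, -1, 1, 0, 1],
        [0, 0, 1, -1, -1, 0, 1, -1],
        [1, 1, 0, 0, -1, 1, -1, 0],
        [-1, 0, 1, 1, -1, 0, 1, 1],
        [0, 1, 0, 1, 1, 1, 0, 0],
        [1, 0, 1, 0, 0, 0, 1, 1],
        [0, 1, 0, 1, 1, 1, 0, 0],
        [1, 0, -1, 0, 0, 0, 1, 1],
        [0, 1, 0, 1, 1, 1, -1, 0],
    ], dtype=np.int8)
    return build_matrix(
        calls,
        positions=[100, 101, 150, 200, 201, 50, 51, 52],
        chroms=["1"] * 5 + ["2"] * 3,
        anc=["A", "G", "A", "C", "G", "A", "T", "G"],
        der=["T", "C", "C", "T", "A", "C", "A", "T"],
        chrom_lengths={"1": 1000.0, "2": 500.0},
    )


# -- transversion filter ----------------------------------------------------

def test_transversion_filter_drops_transitions(mixed_matrix):
    out = gt.filter_transversions(mixed_matrix)
    # C/T at 200 and G/A at 201 are transitions
    assert list(out.sites["pos"]) == [100, 101, 150, 50, 51, 52]


def test_transversion_counts():
    m = build_matrix(np.zeros((2, 5), np.int8),
                     anc=["C", "A", "G", "A", "G"],
                     der=["T", "T", "A", "C", "T"])
    out = gt.filter_transversions(m)
    assert out.n_sites == 3  # 2 transitions (C/T, G/A) removed


# -- missingness filter -----------------------------------------------------

def test_missingness_boundary_is_inclusive():
    # 3/10 missing == 30%: dropped; 2/10: kept
    calls = np.zeros((10, 2), np.int8)
    calls[:3, 0] = -1
    calls[:2, 1] = -1
    out = gt.filter_missingness(build_matrix(calls), 0.30)
    assert list(out.sites["pos"]) == [101]


def test_missingness_max_one_keeps_any_called_site():
    calls = np.full((4, 1), -1, np.int8)
    calls[0, 0] = 1
    out = gt.filter_missingness(build_matrix(calls), 1.0)
    assert out.n_sites == 1


# -- adjacent-site thinning -------------------------------------------------

def test_thin_adjacent_keeps_one_per_run(mixed_matrix):
    out = gt.thin_adjacent(mixed_matrix, seed=0)
    pos = list(out.sites["pos"])
    assert len(pos) == 4                    # {100,101}+{150}+{200,201}+{50,51,52}
    assert 150 in pos
    assert sum(p in (100, 101) for p in pos) == 1
    assert sum(p in (200, 201) for p in pos) == 1
    assert sum(p in (50, 51, 52) for p in pos) == 1


def test_thin_adjacent_noop_without_adjacency():
    m = build_matrix(np.zeros((2, 3), np.int8), positions=[10, 20, 30])
    out = gt.thin_adjacent(m, seed=1)
    assert list(out.sites["pos"]) == [10, 20, 30]


@settings(max_examples=50, deadline=None)
@given(st.sets(st.integers(1, 60), min_size=1, max_size=25),
       st.integers(0, 2**31 - 1))
def test_thin_adjacent_matches_run_count_and_breaks_adjacency(positions, seed):
    pos = sorted(positions)
    m = build_matrix(np.zeros((2, len(pos)), np.int8), positions=pos)
    out = gt.thin_adjacent(m, seed=seed)
    runs = 1 + sum(b - a > 1 for a, b in zip(pos, pos[1:]))
    assert out.n_sites == runs
    kept = out.sites["pos"].to_numpy()
    assert np.all(np.diff(kept) > 1)


# -- polarization -----------------------------------------------------------

def test_polarize_orients_drops_and_swaps(mixed_matrix):
    og = pd.DataFrame({
        "chrom": ["1", "1", "1"], "pos": [100, 101, 150],
        "og1": ["T", "G", "C"], "og2": ["T", "C", "C"], "og3": ["T", "G", "."],
    })
    out = gt.polarize(mixed_matrix, og)
    # 100: outgroups agree on T (current der) -> kept, swapped
    # 101: outgroups disagree (G,C,G) -> dropped
    # 150: non-missing outgroups agree on C (current der) -> kept, swapped
    assert list(out.sites["pos"]) == [100, 150]
    assert list(out.sites["anc"]) == ["T", "C"]
    col100 = out.calls[:, 0]
    orig = mixed_matrix.calls[:, 0]
    assert np.all(col100[orig == 1] == 0)
    assert np.all(col100[orig == 0] == 1)
    assert np.all(col100[orig == -1] == -1)


def test_polarize_drops_allele_not_in_site():
    m = build_matrix(np.zeros((2, 1), np.int8), positions=[100],
                     anc=["A"], der=["T"])
    og = pd.DataFrame({"chrom": ["1"], "pos": [100],
                       "og1": ["G"], "og2": ["G"], "og3": ["G"]})
    assert gt.polarize(m, og).n_sites == 0


def test_polarize_require_all_outgroups():
    m = build_matrix(np.zeros((2, 1), np.int8), positions=[100])
    og = pd.DataFrame({"chrom": ["1"], "pos": [100],
                       "og1": ["A"], "og2": ["A"], "og3": ["."]})
    assert gt.polarize(m, og).n_sites == 1
    assert gt.polarize(m, og, require_all=True).n_sites == 0


# -- pseudo-haploid calling and dropout -------------------------------------

def test_pseudo_haploid_call_min_reads():
    rng = np.random.default_rng(0)
    assert gt.pseudo_haploid_call(1, 0, rng=rng) == -1
    assert gt.pseudo_haploid_call(0, 5, rng=rng) == 1
    assert gt.pseudo_haploid_call(5, 0, rng=rng) == 0


def test_pseudo_haploid_call_balanced_counts_draw_half():
    rng = np.random.default_rng(1)
    draws = [gt.pseudo_haploid_call(3, 3, rng=rng) for _ in range(10_000)]
    assert np.mean(draws) == pytest.approx(0.5, abs=0.02)


def test_downsample_identity_and_binomial():
    calls = np.ones((10, 1000), np.int8)
    m = build_matrix(calls, positions=range(1, 1001))
    assert gt.downsample_calls(m, 1.0, seed=0) is m
    out = gt.downsample_calls(m, 0.5, seed=0)
    kept = int((out.calls != -1).sum())
    assert kept == pytest.approx(5000, abs=220)  # ~4 sigma of Binomial(1e4, .5)
    out2 = gt.downsample_calls(m, 0.5, seed=0)
    assert np.array_equal(out.calls, out2.calls)
    # callable length rescales so the derived fraction stays unbiased
    assert out.callable_length("s0") == pytest.approx(0.5 * m.callable_length("s0"))


# -- derived fraction -------------------------------------------------------

def test_derived_fraction_arithmetic():
    calls = np.zeros((1, 300), np.int8)
    calls[0, :230] = 1
    m = build_matrix(calls, positions=range(1, 301),
                     chrom_lengths={"1": 1e7})
    assert gt.derived_fraction(m, "s0") == pytest.approx(2.3e-5)
    calls0 = np.zeros((1, 10), np.int8)
    m0 = build_matrix(calls0, chrom_lengths={"1": 1e6})
    assert gt.derived_fraction(m0, "s0") == 0.0


# -- pipeline properties ----------------------------------------------------

def test_filters_idempotent(mixed_matrix):
    for f in (gt.filter_transversions,
              lambda m: gt.filter_missingness(m, 0.30)):
        once = f(mixed_matrix)
        twice = f(once)
        assert list(once.sites["pos"]) == list(twice.sites["pos"])
        assert np.array_equal(once.calls, twice.calls)
    thinned = gt.thin_adjacent(mixed_matrix, seed=3)
    rethinned = gt.thin_adjacent(thinned, seed=4)
    assert list(thinned.sites["pos"]) == list(rethinned.sites["pos"])


def test_canonical_pipeline_monotone_site_counts(mixed_matrix):
    og = pd.DataFrame({
        "chrom": mixed_matrix.sites["chrom"], "pos": mixed_matrix.sites["pos"],
        "og1": mixed_matrix.sites["anc"], "og2": mixed_matrix.sites["anc"],
        "og3": mixed_matrix.sites["anc"],
    })
    counts = [mixed_matrix.n_sites]
    m = gt.filter_transversions(mixed_matrix)
    counts.append(m.n_sites)
    m = gt.polarize(m, og)
    counts.append(m.n_sites)
    m = gt.filter_missingness(m, 0.30)
    counts.append(m.n_sites)
    m = gt.thin_adjacent(m, seed=0)
    counts.append(m.n_sites)
    assert all(b <= a for a, b in zip(counts, counts[1:]))


# -- VCF IO -----------------------------------------------------------------

def test_vcf_round_trip(tmp_path, mixed_matrix):
    path = tmp_path / "m.vcf"
    gt.write_vcf(mixed_matrix, path)
    back = gt.read_vcf(path, metadata=mixed_matrix.samples)
    assert np.array_equal(back.calls, mixed_matrix.calls)
    assert list(back.sites["pos"]) == list(mixed_matrix.sites["pos"])
    assert list(back.sites["anc"]) == list(mixed_matrix.sites["anc"])
    assert back.chrom_lengths == mixed_matrix.chrom_lengths


def test_read_vcf_missing_and_het_handling(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1,length=1000>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
        "1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\t./.\n"
        "1\t200\t.\tG\tC\t.\t.\t.\tGT\t0/1\t0/1\t0/1\n"
        "1\t300\t.\tA\tC,G\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"
    )
    m = gt.read_vcf(vcf)
    assert m.n_sites == 2                      # multi-allelic site dropped
    assert list(m.calls[:, 0]) == [0, 1, -1]
    assert set(m.calls[:, 1]) <= {0, 1}        # het resolved by random draw
    m2 = gt.read_vcf(vcf, het_mode="missing")
    assert list(m2.calls[:, 1]) == [-1, -1, -1]
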