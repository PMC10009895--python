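"""Pseudoalignment, EM abundance estimation, TPM, and expression calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from allovax.hla import TranscriptRecord
from allovax.quantify import (
    AbundanceTable,
    EquivalenceClassCounts,
    build_index,
    call_expressed,
    compute_tpm,
    em_abundances,
    fold_change,
    pseudoalign,
    quantify_reads,
)
from allovax.simulate import SimulationConfig, make_allele_pair, simulate_reads


def _tx(tid, seq):
    return TranscriptRecord(id=tid, sequence=seq)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_kmers(seq, k):
    """Independent oracle: canonical k-mer set by direct string enumeration."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        out.add(min(km, km.translate(comp)[::-1]))
    return out


def grid_search_ml(ec_counts, eff_lengths, ids, step=0.001):
    """Maximum-likelihood read fractions by dense simplex search.

    Independent of the EM path: evaluates the mixture log-likelihood
    ``sum_ec c_ec * log(sum_{t in ec} theta_t / l_t)`` at every grid
    point of the read-fraction simplex and returns the argmax.
    """
    T = len(ids)
    inv_l = np.array([1.0 / eff_lengths[t] for t in ids])
    fracs = np.arange(0.0, 1.0 + step / 2, step)
    if T == 2:
        theta = np.stack([fracs, 1.0 - fracs], axis=1)
    elif T == 3:
        a, b = np.meshgrid(fracs, fracs, indexing="ij")
        a, b = a.ravel(), b.ravel()
        keep = a + b <= 1.0 + 1e-12
        theta = np.stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]], axis=1)
    else:
        raise ValueError("oracle supports 2-3 transcripts")
    pos = {t: i for i, t in enumerate(ids)}
    ll = np.zeros(theta.shape[0])
    w = theta * inv_l[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        for ec, c in ec_counts.items():
            m = [pos[t] for t in ec]
            ll += c * np.log(w[:, m].sum(axis=1))
    ll[~np.isfinite(ll)] = -np.inf
    return theta[np.argmax(ll)]


class TestBuildIndex:
    def test_single_transcript_every_kmer_maps_to_it(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 100)
        idx = build_index([_tx("t1", seq)], k=21, read_length=50)
        assert len(idx.kmer_map) == len(brute_force_kmers(seq, 21))
        assert all(s == frozenset({"t1"}) for s in idx.kmer_map.values())
        assert idx.eff_lengths["t1"] == 100 - 50 + 1

    def test_identical_sequences_share_every_kmer(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 80)
        idx = build_index([_tx("a", seq), _tx("b", seq)], k=15, read_length=50)
        assert all(s == frozenset({"a", "b"}) for s in idx.kmer_map.values())

    def test_single_middle_mismatch_gives_k_specific_kmers(self):
        """Two transcripts differing at one middle base: exactly k k-mer
        positions per transcript overlap the difference, verified against
        brute-force enumeration."""
        rng = np.random.default_rng(2)
        k = 15
        s1 = _random_seq(rng, 200)
        mid = 100
        alt = next(b for b in "ACGT" if b != s1[mid])
        s2 = s1[:mid] + alt + s1[mid + 1 :]
        idx = build_index([_tx("t1", s1), _tx("t2", s2)], k=k, read_length=100)
        k1, k2 = brute_force_kmers(s1, k), brute_force_kmers(s2, k)
        assert len(k1 - k2) == k
        specific_t1 = [
            c for c, s in idx.kmer_map.items() if s == frozenset({"t1"})
        ]
        assert len(specific_t1) == k

    def test_short_transcript_rejected(self):
        with pytest.raises(ValueError, match="t1"):
            build_index([_tx("t1", "ACGTACGT")], k=21, read_length=50)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            build_index([_tx("t1", "ACGT" * 20)], k=20, read_length=50)

    def test_effective_length_floor(self):
        idx = build_index([_tx("t1", "ACGT" * 10)], k=21, read_length=150)
        assert idx.eff_lengths["t1"] == 1.0


class TestPseudoalign:
    @pytest.fixture(scope="class")
    def allele_index(self):
        a1, a2 = make_allele_pair(600, 0.92, seed=5)
        rng = np.random.default_rng(6)
        bg = _tx("bg1", _random_seq(rng, 500))
        return (a1, a2, bg, build_index([a1, a2, bg], k=21, read_length=100))

    def test_unique_read_gives_singleton_class(self, allele_index):
        a1, a2, bg, idx = allele_index
        read = bg.sequence[50:150]
        ecs = pseudoalign([read], idx)
        assert ecs.counts == {("bg1",): 1}
        assert ecs.unassigned == 0

    def test_shared_region_read_gives_pair_class(self):
        """A read from a region identical between two homologous alleles is
        compatible with both; the divergent region stays allele-specific."""
        rng = np.random.default_rng(8)
        base = _random_seq(rng, 600)
        # ~92% overall identity with every substitution in the first half
        mutated = list(base)
        for i in rng.choice(300, size=48, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        a1 = _tx("allele1", base)
        a2 = _tx("allele2", "".join(mutated))
        idx = build_index([a1, a2], k=21, read_length=100)
        shared_read = base[450:550]
        ecs = pseudoalign([shared_read], idx)
        assert ecs.counts == {("allele1", "allele2"): 1}
        specific_read = base[0:100]
        ecs = pseudoalign([specific_read], idx)
        assert ecs.counts == {("allele1",): 1}

    def test_foreign_read_unassigned(self, allele_index):
        *_, idx = allele_index
        rng = np.random.default_rng(7)
        for _ in range(5):
            ecs = pseudoalign([_random_seq(rng, 100)], idx)
            if ecs.unassigned == 1 and not ecs.counts:
                return
        raise AssertionError("random reads kept aligning")

    def test_read_count_conserved(self, allele_index):
        a1, a2, bg, idx = allele_index
        reads = [a1.sequence[i : i + 100] for i in range(0, 400, 7)]
        ecs = pseudoalign(reads, idx)
        assert ecs.total_assigned + ecs.unassigned == len(reads)

    def test_all_n_read_unassigned(self, allele_index):
        *_, idx = allele_index
        ecs = pseudoalign(["N" * 100], idx)
        assert ecs.unassigned == 1

    def test_invalid_character_is_an_error(self, allele_index):
        *_, idx = allele_index
        with pytest.raises(ValueError, match="non-ACGTN"):
            pseudoalign(["ACGTX" + "A" * 95], idx)

    def test_error_kmers_are_skipped_not_vetoed(self, allele_index):
        a1, a2, bg, idx = allele_index
        read = list(bg.sequence[100:200])
        read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[50]]
        ecs = pseudoalign(["".join(read)], idx)
        assert ecs.counts == {("bg1",): 1}


def _index_for(ids, length=400, read_length=100, seed=0):
    rng = np.random.default_rng(seed)
    txs = [_tx(t, _random_seq(rng, length)) for t in ids]
    return build_index(txs, k=21, read_length=read_length)


class TestEm:
    def test_single_transcript_gets_all_reads(self):
        idx = _index_for(["t1"])
        ecs = EquivalenceClassCounts(counts={("t1",): 1000})
        tab = em_abundances(ecs, idx)
        assert tab.est_counts["t1"] == pytest.approx(1000)

    def test_fully_shared_class_splits_by_symmetry(self):
        idx = _index_for(["t1", "t2"], length=400)
        idx.eff_lengths = {"t1": 300.0, "t2": 300.0}
        ecs = EquivalenceClassCounts(counts={("t1", "t2"): 100})
        tab = em_abundances(ecs, idx)
        assert tab.est_counts["t1"] == pytest.approx(50)
        assert tab.est_counts["t2"] == pytest.approx(50)

    def test_agrees_with_grid_search_oracle(self):
        """EM matches brute-force likelihood maximization on the
        {t1}:30, {t1,t2}:70 instance (equal effective lengths)."""
        idx = _index_for(["t1", "t2"])
        idx.eff_lengths = {"t1": 250.0, "t2": 250.0}
        counts = {("t1",): 30, ("t1", "t2"): 70}
        tab = em_abundances(
            EquivalenceClassCounts(counts=counts), idx, tol=1e-12, max_iter=5000
        )
        est_frac = tab.est_counts / tab.est_counts.sum()
        oracle = grid_search_ml(counts, idx.eff_lengths, idx.ids)
        assert est_frac.to_numpy() == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_instances(self, seed):
        """On random <=3-transcript, <=5-class instances EM agrees with the
        grid-search maximum within 1e-3 relative abundance."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 4))
        ids = [f"t{i}" for i in range(T)]
        idx = _index_for(ids, seed=seed + 100)
        idx.eff_lengths = {
            t: float(rng.integers(100, 400)) for t in ids
        }
        # singleton classes for every transcript keep the MLE identifiable
        # and interior; add up to 2 random ambiguous classes (<=5 total)
        counts = {(t,): int(rng.integers(10, 100)) for t in ids}
        multis = [
            s for r in range(2, T + 1) for s in itertools.combinations(ids, r)
        ]
        for _ in range(int(rng.integers(0, 3))):
            s = multis[int(rng.integers(0, len(multis)))]
            counts[s] = counts.get(s, 0) + int(rng.integers(10, 100))
        tab = em_abundances(
            EquivalenceClassCounts(counts=counts), idx, tol=1e-12, max_iter=20000
        )
        est_frac = (tab.est_counts / tab.est_counts.sum()).to_numpy()
        oracle = grid_search_ml(counts, idx.eff_lengths, ids, step=0.0005)
        assert np.abs(est_frac - oracle).max() < 1e-3

    def test_count_conservation_each_iteration(self):
        idx = _index_for(["t1", "t2", "t3"])
        counts = {("t1",): 11, ("t1", "t2"): 23, ("t2", "t3"): 41, ("t3",): 7}
        tab = em_abundances(EquivalenceClassCounts(counts=counts), idx)
        assert tab.est_counts.sum() == pytest.approx(82, rel=1e-9)

    def test_loglik_non_decreasing(self):
        idx = _index_for(["t1", "t2", "t3"])
        idx.eff_lengths = {"t1": 50.0, "t2": 200.0, "t3": 301.0}
        counts = {("t1",): 9, ("t1", "t2"): 55, ("t2", "t3"): 31, ("t3",): 2}
        tab = em_abundances(
            EquivalenceClassCounts(counts=counts), idx, tol=1e-12
        )
        diffs = np.diff(tab.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_non_convergence_flagged(self):
        idx = _index_for(["t1", "t2"])
        counts = {("t1",): 30, ("t1", "t2"): 70}
        tab = em_abundances(
            EquivalenceClassCounts(counts=counts), idx, tol=1e-15, max_iter=3
        )
        assert not tab.converged
        assert tab.n_iter == 3


class TestTpmAndCalls:
    def _table(self, counts, eff):
        df = pd.DataFrame(
            {"est_counts": counts, "eff_length": eff, "tpm": np.nan},
            index=[f"t{i}" for i in range(len(counts))],
        )
        return AbundanceTable(df=df)

    def test_single_transcript_is_a_million(self):
        tab = compute_tpm(self._table([42.0], [100.0]))
        assert tab.tpm.iloc[0] == pytest.approx(1e6)

    def test_closed_form_two_transcripts(self):
        tab = compute_tpm(self._table([10.0, 10.0], [100.0, 200.0]))
        assert tab.tpm.to_numpy() == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_all_zero_counts_no_division_error(self):
        tab = compute_tpm(self._table([0.0, 0.0], [100.0, 200.0]))
        assert (tab.tpm == 0).all()

    def test_tpm_sums_to_a_million(self):
        rng = np.random.default_rng(3)
        tab = compute_tpm(
            self._table(rng.uniform(1, 100, 20), rng.uniform(50, 500, 20))
        )
        assert tab.tpm.sum() == pytest.approx(1e6, rel=1e-9)

    @pytest.mark.parametrize(
        "tpm, expressed", [(0.99, False), (1.0, False), (1.01, True)]
    )
    def test_strict_threshold_boundary(self, tpm, expressed):
        tab = self._table([1.0], [100.0])
        tab.df["tpm"] = [tpm]
        calls = call_expressed(tab, threshold=1.0)
        assert calls[0].expressed is expressed

    def test_negative_threshold_rejected(self):
        tab = compute_tpm(self._table([1.0], [100.0]))
        with pytest.raises(ValueError):
            call_expressed(tab, threshold=-1)


class TestFoldChange:
    def _table(self, tpms):
        df = pd.DataFrame(
            {
                "est_counts": np.ones(len(tpms)),
                "eff_length": np.full(len(tpms), 100.0),
                "tpm": tpms,
            },
            index=[f"t{i}" for i in range(len(tpms))],
        )
        return AbundanceTable(df=df)

    def test_identical_tables_give_unity(self):
        t = self._table([5.0, 50.0])
        assert (fold_change(t, t) == 1.0).all()

    def test_tenfold_with_vanishing_pseudocount(self):
        c = self._table([10.0, 100.0])
        t = self._table([100.0, 1000.0])
        fc = fold_change(c, t, pseudocount=1e-9)
        assert fc.to_numpy() == pytest.approx([10.0, 10.0], rel=1e-6)

    def test_mismatched_transcripts_rejected(self):
        c = self._table([1.0])
        t = self._table([1.0, 2.0])
        with pytest.raises(ValueError):
            fold_change(c, t)


class TestSmallScaleRecovery:
    def test_known_abundances_recovered(self):
        """Reads simulated from known TPMs over a transcriptome with a
        92%-identity allele pair are quantified back within 15%."""
        rng = np.random.default_rng(11)
        a1, a2 = make_allele_pair(900, 0.92, seed=11)
        txs = [
            _tx(f"bg{i}", _random_seq(rng, 700)) for i in range(6)
        ] + [a1, a2]
        ids = [t.id for t in txs]
        raw = np.array([80000, 120000, 150000, 90000, 200000, 160000, 120000, 80000.0])
        tpm = raw / raw.sum() * 1e6
        cfg = SimulationConfig(seed=12, n_reads=40_000, error_rate=0.002)
        reads, _ = simulate_reads(txs, dict(zip(ids, tpm)), cfg)
        idx = build_index(txs, k=21, read_length=150)
        tab = quantify_reads(reads, idx)
        rel = np.abs(tab.df.loc[ids, "tpm"].to_numpy() - tpm) / tpm
        assert rel.max() < 0.15
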