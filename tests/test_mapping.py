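"""k-mer index, flank alignment and per-barcode insertion calling."""

from __future__ import annotations

import numpy as np
import pytest

from coldscreen.barcodes import CassetteSpec
from coldscreen.mapping import (
    Candidate,
    FlankRecord,
    MapParams,
    associate_pairs,
    build_kmer_index,
    call_insertions,
    map_flank,
    revcomp,
)


def random_genome(rng: np.random.Generator, lens: dict[str, int]) -> dict[str, str]:
    return {
        name: "".join(rng.choice(list("ACGT"), size=n))
        for name, n in lens.items()
    }


def bruteforce_best(flank: str, genome: dict[str, str]) -> list[Candidate]:
    """Full-scan Hamming aligner over every position and both strands,
    vectorised but logically independent of the seeded aligner."""
    L = len(flank)
    fl = np.frombuffer(flank.encode(), dtype=np.uint8)
    out = []
    for chrom, seq in genome.items():
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mms = (windows != fl).sum(axis=1)
            for off in np.flatnonzero(mms == mms.min()):
                mm = int(mms[off])
                # offset in the (possibly reverse-complemented) string back
                # to the genomic coordinate of the flank's first base
                pos = off + 1 if strand == "+" else len(seq) - off
                out.append(Candidate(chrom, int(pos), strand, L - 2 * mm, mm))
    out.sort(key=lambda c: (c.mismatches, c.chrom, c.pos, c.strand))
    best_mm = out[0].mismatches
    return [c for c in out if c.mismatches == best_mm]


class TestKmerIndex:
    def test_tiny_genome_enumerable_by_hand(self):
        idx = build_kmer_index({"c": "ACGTACGT"}, k=4)
        # forward ACGT at 1 and 5; the sequence is its own reverse
        # complement, so ACGT also occurs on - at first-base coords 8 and 4
        assert set(idx.lookup("ACGT")) == {("c", 1, "+"), ("c", 5, "+"), ("c", 8, "-"), ("c", 4, "-")}
        assert set(idx.lookup("CGTA")) == {("c", 2, "+"), ("c", 7, "-")}
        assert set(idx.lookup("GTAC")) == {("c", 3, "+"), ("c", 6, "-")}
        assert idx.lookup("AAAA") == []

    def test_k_longer_than_chromosome_gives_empty_index(self):
        idx = build_kmer_index({"c": "ACGT"}, k=10)
        assert len(idx.occurrences) == 0

    def test_non_acgt_kmers_skipped(self):
        idx = build_kmer_index({"c": "ACGTNACGT"}, k=4)
        assert idx.skipped_kmers > 0
        assert all("N" not in kmer for kmer in idx.occurrences)

    def test_every_occurrence_rereads_correctly(self):
        """Exhaustive oracle: each stored occurrence, re-read from the
        genome at its coordinate and strand, reproduces the k-mer."""
        rng = np.random.default_rng(2)
        genome = random_genome(rng, {"chr1": 6000, "chr2": 4000})
        k = 13
        idx = build_kmer_index(genome, k)
        n_checked = 0
        for kmer, occs in idx.occurrences.items():
            for chrom, pos, strand in occs:
                seq = genome[chrom]
                if strand == "+":
                    assert seq[pos - 1 : pos - 1 + k] == kmer
                else:
                    assert revcomp(seq[pos - k : pos]) == kmer
                n_checked += 1
        # both strands fully represented
        assert n_checked == 2 * sum(len(s) - k + 1 for s in genome.values())


@pytest.fixture(scope="module")
def genome():
    return random_genome(np.random.default_rng(3), {"chr1": 12000, "chr2": 8000})


@pytest.fixture(scope="module")
def index(genome):
    return build_kmer_index(genome)


class TestMapFlank:

    def test_exact_flank_maps_to_origin_with_zero_mismatches(self, genome, index):
        flank = genome["chr1"][999:1059]
        top = map_flank(flank, index)[0]
        assert (top.chrom, top.pos, top.strand, top.mismatches) == ("chr1", 1000, "+", 0)

    def test_minus_strand_flank_maps_to_its_first_base(self, genome, index):
        # flank reading leftward whose first genomic base is at 2059
        flank = revcomp(genome["chr1"][2000:2060])
        top = map_flank(flank, index)[0]
        assert (top.chrom, top.pos, top.strand) == ("chr1", 2060, "-")

    def test_random_flank_is_unmapped(self, index):
        rng = np.random.default_rng(9)
        flank = "".join(rng.choice(list("ACGT"), size=60))
        assert map_flank(flank, index) == []

    def test_flank_shorter_than_k_is_unmapped(self, index):
        assert map_flank("ACGTACGT", index) == []

    def test_strand_roundtrip(self, genome, index):
        """Mapping the reverse complement of a flank yields the same
        genomic segment on the flipped strand."""
        flank = genome["chr2"][4999:5059]
        fwd = map_flank(flank, index)[0]
        rev = map_flank(revcomp(flank), index)[0]
        assert fwd.strand == "+" and rev.strand == "-"
        assert rev.chrom == fwd.chrom
        assert rev.pos == fwd.pos + len(flank) - 1  # same segment, other end

    def test_agrees_with_fullscan_hamming_oracle(self, genome, index):
        """On a 20 kb genome the seeded aligner's unique best locus equals
        the brute-force full-scan best for flanks with 0-2 substitutions."""
        rng = np.random.default_rng(17)
        chroms = list(genome)
        for _ in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, len(genome[chrom]) - 60))
            flank = genome[chrom][start : start + 60]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                flank = revcomp(flank)
            n_sub = int(rng.integers(0, 3))
            fl = list(flank)
            for p in rng.choice(60, size=n_sub, replace=False):
                fl[p] = "ACGT"["ACGT".index(fl[p]) - rng.integers(1, 4)]
            flank = "".join(fl)
            got = map_flank(flank, index)
            oracle = bruteforce_best(flank, genome)
            if len(oracle) == 1 and (len(got) < 2 or got[0].score > got[1].score):
                assert got, f"seeded aligner missed {oracle[0]}"
                assert (got[0].chrom, got[0].pos, got[0].strand) == (
                    oracle[0].chrom,
                    oracle[0].pos,
                    oracle[0].strand,
                )
                assert got[0].mismatches == oracle[0].mismatches


class TestAssociatePairs:
    SPEC = CassetteSpec(barcode_len=12)

    def _fastq(self, path, seqs):
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@p{i}\n{s}\n+\n{'I' * len(s)}\n")

    def test_valid_pair_yields_record_and_bad_pair_is_tallied(self, tmp_path):
        spec = self.SPEC
        cassette = spec.upstream_anchor + "ACGTACGTACGT" + spec.downstream_anchor
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        self._fastq(r1, [cassette, "T" * 60])
        self._fastq(r2, ["ACGT" * 15, "ACGT" * 15])
        records, tally = associate_pairs(r1, r2, spec, source_sample="CK1")
        assert len(records) == 1
        assert records[0] == FlankRecord("ACGTACGTACGT", "ACGT" * 15, "CK1")
        assert tally == {"pairs": 2, "kept": 1, "dropped": {"anchor-missing": 1}}

    def test_cassette_remnant_stripped_from_flank(self, tmp_path):
        spec = self.SPEC
        cassette = spec.upstream_anchor + "ACGTACGTACGT" + spec.downstream_anchor
        flank = spec.downstream_anchor + "TTTTCCCCGGGG"
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        self._fastq(r1, [cassette])
        self._fastq(r2, [flank])
        records, _ = associate_pairs(r1, r2, spec)
        assert records[0].flank == "TTTTCCCCGGGG"

    def test_mate_count_mismatch_raises(self, tmp_path):
        spec = self.SPEC
        cassette = spec.upstream_anchor + "ACGTACGTACGT" + spec.downstream_anchor
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        self._fastq(r1, [cassette, cassette])
        self._fastq(r2, ["ACGT" * 15])
        with pytest.raises(ValueError, match="mate-count mismatch"):
            associate_pairs(r1, r2, spec)


@pytest.fixture(scope="module")
def call_genome():
    return random_genome(np.random.default_rng(23), {"chr1": 9000})


@pytest.fixture(scope="module")
def call_index(call_genome):
    return build_kmer_index(call_genome)


class TestCallInsertions:

    def _rec(self, genome, barcode, start, n):
        flank = genome["chr1"][start - 1 : start + 59]
        return [FlankRecord(barcode, flank) for _ in range(n)]

    def test_concordant_records_give_unique_call(self, call_genome, call_index):
        calls = call_insertions(self._rec(call_genome, "B1", 500, 10), call_index)
        (c,) = calls
        assert (c.status, c.chrom, c.pos, c.strand, c.support) == ("unique", "chr1", 500, "+", 10)

    def test_even_split_is_ambiguous(self, call_genome, call_index):
        recs = self._rec(call_genome, "B1", 500, 5) + self._rec(call_genome, "B1", 3000, 5)
        (c,) = call_insertions(recs, call_index)
        assert c.status == "ambiguous"

    def test_unmappable_records_give_unmapped(self, call_index):
        recs = [FlankRecord("B1", "AC" * 30)]
        (c,) = call_insertions(recs, call_index)
        assert c.status == "unmapped" and c.n_mapped == 0

    def test_minority_disagreement_below_agree_frac_is_conflicting(self, call_genome, call_index):
        recs = self._rec(call_genome, "B1", 500, 6) + self._rec(call_genome, "B1", 3000, 4)
        (c,) = call_insertions(recs, call_index)  # 0.6 < min_agree_frac=0.8
        assert c.status == "conflicting"

    def test_single_record_below_min_support_is_not_unique(self, call_genome, call_index):
        (c,) = call_insertions(self._rec(call_genome, "B1", 500, 1), call_index)
        assert c.status == "conflicting" and c.support == 1

    def test_nearby_positions_pool_within_slop(self, call_genome, call_index):
        recs = self._rec(call_genome, "B1", 500, 3) + self._rec(call_genome, "B1", 502, 2)
        (c,) = call_insertions(recs, call_index)
        assert c.status == "unique" and c.support == 5 and c.pos == 500

    def test_raising_min_support_never_adds_unique_calls(self, call_genome, call_index):
        rng = np.random.default_rng(31)
        recs = []
        for b in range(20):
            start = int(rng.integers(1, 8000))
            recs += self._rec(call_genome, f"B{b}", start, int(rng.integers(1, 6)))
        uniques = []
        for ms in (1, 2, 3, 4, 6):
            params = MapParams(min_support=ms)
            calls = call_insertions(recs, call_index, params)
            uniques.append(sum(c.status == "unique" for c in calls))
        assert uniques == sorted(uniques, reverse=True)

    def test_noiseless_simulation_recovers_every_truth_locus(self, noiseless_sim):
        """With zero sequencing error, every barcode with enough pairs is
        called unique at exactly the simulated insertion locus."""
        from conftest import small_config

        cfg = small_config()
        index = build_kmer_index(noiseless_sim.genome)
        spec = cfg.cassette_spec()
        records = []
        for sample, (r1, r2) in noiseless_sim.emitted.leap_fastqs.items():
            recs, tally = associate_pairs(r1, r2, spec, source_sample=sample)
            assert tally["kept"] == tally["pairs"]
            records.extend(recs)
        calls = call_insertions(records, index)
        truth = noiseless_sim.truth.set_index("barcode")
        pair_counts = {}
        for r in records:
            pair_counts[r.barcode] = pair_counts.get(r.barcode, 0) + 1
        for c in calls:
            t = truth.loc[c.barcode]
            if pair_counts[c.barcode] >= 2 and not t["flank_truncated"]:
                assert c.status == "unique", c
                assert (c.chrom, c.pos, c.strand) == (t["chrom"], t["pos"], t["strand"])
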