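"""Peak calling, promoter assignment and PWM scanning."""

import numpy as np
import pytest

from ribolife import chip, simulate
from ribolife.annotation import PromoterWindow, TranscriptModel, promoter_window, revcomp


def _bump_tracks(L=20_000, summits=(), mult=10.0, base=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.arange(L, dtype=float)
    signal = np.ones(L)
    for s in summits:
        signal += mult * np.exp(-((x - s) ** 2) / (2 * 75.0 ** 2))
    chip_cov = rng.poisson(base * signal).astype(float)
    input_cov = rng.poisson(base, size=L).astype(float)
    return {"chr1": chip_cov}, {"chr1": input_cov}


class TestCallPeaks:
    def test_planted_bump_recovered(self):
        c, i = _bump_tracks(summits=[8000])
        peaks = chip.call_peaks(c, i)
        assert len(peaks) == 1
        assert abs(peaks[0].summit - 8000) <= 10
        assert peaks[0].enrichment > 4

    def test_null_identical_tracks_no_peaks(self):
        rng = np.random.default_rng(1)
        t = {"chr1": rng.poisson(5, size=20_000).astype(float)}
        assert chip.call_peaks(t, {"chr1": t["chr1"].copy()}) == []

    def test_distant_bumps_not_merged(self):
        c, i = _bump_tracks(L=30_000, summits=[5000, 20_000])
        peaks = chip.call_peaks(c, i)
        assert len(peaks) == 2
        assert abs(peaks[0].summit - 5000) <= 10
        assert abs(peaks[1].summit - 20_000) <= 10

    def test_zero_depth_input_raises(self):
        c = {"chr1": np.ones(1000)}
        with pytest.raises(ValueError):
            chip.call_peaks(c, {"chr1": np.zeros(1000)})


class TestAssignment:
    def _peak(self, summit):
        return chip.Peak("chr1", summit - 50, summit + 50, summit, 5.0)

    def test_unique_ambiguous_unassigned_partition(self):
        promoters = [
            PromoterWindow("a", "chr1", "+", (4000, 5000), 1000),
            # divergent pair sharing [9000, 10000) vs [9500, 10500)
            PromoterWindow("b", "chr1", "+", (9000, 10_000), 1000),
            PromoterWindow("c", "chr1", "-", (9500, 10_500), 1000),
        ]
        peaks = [self._peak(4750), self._peak(9700), self._peak(20_000)]
        annotated, targets = chip.assign_peaks_to_genes(peaks, promoters)
        assert [p.ambiguity for p in annotated] == ["unique", "ambiguous", "unassigned"]
        assert targets == ["a"]
        counts = {k: sum(p.ambiguity == k for p in annotated)
                  for k in ("unique", "ambiguous", "unassigned")}
        assert sum(counts.values()) == len(peaks)

    def test_summit_upstream_of_single_gene(self):
        promoters = [PromoterWindow("a", "chr1", "+", (4000, 5000), 1000)]
        (p,), targets = chip.assign_peaks_to_genes([self._peak(4750)], promoters)
        assert p.assigned_gene == "a"

    def test_summit_beyond_window_unassigned(self):
        promoters = [PromoterWindow("a", "chr1", "+", (4000, 5000), 1000)]
        (p,), targets = chip.assign_peaks_to_genes([self._peak(3500)], promoters)
        assert p.ambiguity == "unassigned"


class TestSummitDistance:
    @pytest.mark.parametrize(
        "strand,cds,summit,expected",
        [
            ("+", (5000, 5300), 4750, 250),
            ("-", (1700, 2000), 2100, 100),
            ("+", (5000, 5300), 5000, 0),
        ],
    )
    def test_signed_distance(self, strand, cds, summit, expected):
        gene = TranscriptModel("g", "chr1", strand, cds)
        peak = chip.Peak("chr1", summit - 10, summit + 10, summit, 2.0)
        assert chip.summit_distance_to_start(peak, gene) == expected


def _brute_force_best(seq, pwm):
    """Score every window on both strands explicitly."""
    lo = {b: pwm.log_odds[i] for i, b in enumerate("ACGTN")}
    best = None
    for strand in "+-":
        for w in range(len(seq) - pwm.length + 1):
            site = seq[w: w + pwm.length]
            if strand == "-":
                site = revcomp(site)
            s = sum(lo[b][i] for i, b in enumerate(site))
            cand = (s, -w, 0 if strand == "+" else -1, strand)
            if best is None or cand[:3] > best[:3]:
                best = cand
    return best[0], -best[1], best[3]


class TestScanPwm:
    def test_consensus_hit_score_and_position(self):
        rng = np.random.default_rng(7)
        consensus = "TGACTCA"
        pwm = chip.PWM("m", _one_hot(consensus), pseudocount=0.01)
        seq = _random_no_motif(rng, 500, consensus)
        planted = 200
        seq = seq[:planted] + consensus + seq[planted + len(consensus):]
        hit = chip.scan_pwm(seq, pwm)
        assert hit.position == planted
        assert hit.strand == "+"
        # each consensus column scores ~log2(1/0.25) = 2 bits, pseudocount-shrunk
        assert abs(hit.score - pwm.length * np.log2(4 * (1 + 0.01) / 1.04)) < 0.1

    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = chip.PWM("u", np.full((4, 6), 0.25), pseudocount=0.0)
        hit = chip.scan_pwm("ACGTACGTACGT", pwm)
        assert abs(hit.score) < 1e-12

    def test_reverse_strand_hit_same_score(self):
        rng = np.random.default_rng(8)
        consensus = "TGACTCA"
        pwm = chip.PWM("m", _one_hot(consensus), pseudocount=0.01)
        back = _random_no_motif(rng, 400, consensus)
        fwd = back[:100] + consensus + back[100 + 7: 400]
        rev = back[:100] + revcomp(consensus) + back[100 + 7: 400]
        h_f = chip.scan_pwm(fwd, pwm)
        h_r = chip.scan_pwm(rev, pwm)
        assert h_r.strand == "-"
        assert np.isclose(h_f.score, h_r.score)

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(9)
        for trial in range(3):
            K = int(rng.integers(5, 12))
            freqs = rng.dirichlet(np.ones(4), size=K).T
            pwm = chip.PWM(f"m{trial}", freqs)
            seq = "".join(rng.choice(list("ACGTN"), size=2000, p=[0.24] * 4 + [0.04]))
            hit = chip.scan_pwm(seq, pwm)
            score, pos, strand = _brute_force_best(seq, pwm)
            assert np.isclose(hit.score, score)
            assert hit.position == pos
            assert hit.strand == strand

    def test_revcomp_sequence_preserves_best_score(self):
        rng = np.random.default_rng(10)
        freqs = rng.dirichlet(np.ones(4), size=8).T
        pwm = chip.PWM("m", freqs)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        assert np.isclose(chip.scan_pwm(seq, pwm).score,
                          chip.scan_pwm(revcomp(seq), pwm).score)

    def test_short_sequence_raises(self):
        pwm = chip.PWM("m", np.full((4, 10), 0.25))
        with pytest.raises(ValueError):
            chip.scan_pwm("ACGT", pwm)


class TestConfiguration:
    def _hit(self, pos, score=20.0, motif="m"):
        return chip.MotifHit(motif, score, pos, "+")

    def test_rap1_upstream_of_gcn4(self):
        out = chip.classify_configuration(self._hit(-250), self._hit(-400), 10, 10)
        assert out == "rap1_upstream_of_gcn4"

    def test_gcn4_upstream_of_rap1(self):
        out = chip.classify_configuration(self._hit(-600), self._hit(-100), 10, 10)
        assert out == "gcn4_upstream_of_rap1"

    def test_single_and_none(self):
        assert chip.classify_configuration(self._hit(-250), self._hit(-400, score=5), 10, 10) == "single"
        assert chip.classify_configuration(self._hit(-250, score=1), self._hit(-400, score=5), 10, 10) == "none"


class TestPwmIO:
    def test_tab_round_trip(self, tmp_path):
        pwm = chip.pwm_from_consensus("gcn4", "TGACTCA")
        chip.write_pwm_tab(pwm, tmp_path / "m.pwm")
        back = chip.read_pwm_tab(tmp_path / "m.pwm", motif_id="gcn4")
        assert np.allclose(back.freqs, pwm.freqs, atol=1e-5)
        assert back.consensus == "TGACTCA"

    def test_meme_minimal_parser(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF gcn4\n"
            "letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
            " 0.970 0.010 0.010 0.010\n"
            " 0.010 0.970 0.010 0.010\n"
            " 0.010 0.010 0.970 0.010\n"
        )
        (tmp_path / "m.meme").write_text(text)
        (pwm,) = chip.read_pwm_meme(tmp_path / "m.meme")
        assert pwm.motif_id == "gcn4"
        assert pwm.consensus == "ACG"

    def test_narrowpeak_round_trip(self, tmp_path):
        peaks = [chip.Peak("chr1", 100, 400, 250, 8.5)]
        chip.write_narrowpeak(peaks, tmp_path / "p.np")
        back = chip.read_narrowpeak(tmp_path / "p.np")
        assert back[0].summit == 250 and back[0].start == 100


class TestBedgraphIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        track = {"chr1": rng.poisson(5, size=3000).astype(float)}
        chip.write_bedgraph(track, tmp_path / "t.bg")
        back = chip.read_bedgraph(tmp_path / "t.bg")
        assert np.allclose(back["chr1"], track["chr1"])


def _one_hot(consensus):
    mat = np.zeros((4, len(consensus)))
    for i, b in enumerate(consensus):
        mat["ACGT".index(b), i] = 1.0
    return mat


def _random_no_motif(rng, n, consensus):
    """Random ACGT sequence free of the consensus on either strand."""
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if consensus not in seq and revcomp(consensus) not in seq:
            return seq
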