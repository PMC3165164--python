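import numpy as np
import pytest

from cmprof.alphabet import ALPHABET, BACKGROUND, GAP_CODE
from cmprof.errors import FormatError, InputError
from cmprof.fixtures import simulate_msa
from cmprof.msa_io import (Msa, SequenceProfile, build_profile, read_msa,
                           read_psiblast_pssm, read_ss2, thin_msa, write_msa,
                           write_psiblast_pssm)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class TestReadMsa:
    def test_seed_gap_columns_dropped(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("seed", "ACDE-FGH"), ("x", "ACDEWFGH"), ("y", "AC-EWF-H")])
        msa = read_msa(p)
        assert msa.n == 7
        assert msa.rows[0] == "ACDEFGH"
        assert msa.rows[2] == "AC-EF-H"  # column where seed was gapped is gone

    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        write_fasta(p, [("only", "ACDEFG")])
        msa = read_msa(p)
        assert msa.n_seq == 1 and msa.n == 6 and msa.seed_id == "only"

    def test_ragged_alignment_is_format_error(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        write_fasta(p, [("a", "ACDE"), ("b", "ACD")])
        with pytest.raises(FormatError):
            read_msa(p)

    def test_empty_file_is_input_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(InputError):
            read_msa(p)

    def test_illegal_residues_become_gaps(self, tmp_path, caplog):
        p = tmp_path / "odd.fasta"
        write_fasta(p, [("seed", "ACDEFG"), ("x", "AXBZUO")])
        with caplog.at_level("WARNING"):
            msa = read_msa(p)
        assert msa.rows[1] == "A-----"
        assert any("non-standard" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize("fmt", ["fasta", "stockholm"])
    def test_round_trip_identity(self, fmt, tmp_path, rng):
        msa, _ = simulate_msa(18, 12, seed=int(rng.integers(2**31)))
        p = tmp_path / f"rt.{fmt}"
        write_msa(msa, p, fmt)
        back = read_msa(p, fmt)
        assert back.rows == msa.rows and back.ids == msa.ids


class TestThinMsa:
    def test_all_gap_sequence_removed(self):
        msa = Msa("s", ["s", "g"], ["ACDEF", "-----"])
        assert thin_msa(msa).ids == ["s"]

    def test_exact_duplicate_removed(self):
        msa = Msa("s", ["s", "dup"], ["ACDEF", "ACDEF"])
        assert thin_msa(msa).ids == ["s"]

    def test_planted_clusters_reduce_to_representatives(self, rng):
        # 3 cluster centers ~40% identical; members ~90% identical to centers
        n = 40
        centers = rng.integers(0, 20, size=(3, n))
        centers[1, : int(0.6 * n)] = (centers[0, : int(0.6 * n)] + 1) % 20
        centers[2, : int(0.6 * n)] = (centers[0, : int(0.6 * n)] + 2) % 20
        rows, ids = [], []
        for c in range(3):
            for m in range(4):
                seq = centers[c].copy()
                flip = rng.choice(n, size=3, replace=False)
                seq[flip] = (seq[flip] + 5) % 20
                rows.append("".join(ALPHABET[v] for v in seq))
                ids.append(f"c{c}m{m}")
        msa = Msa(ids[0], ids, rows)
        thinned = thin_msa(msa)
        assert thinned.n_seq == 3
        # brute-force all-pairs identity check on the retained set
        mat = thinned.matrix()
        for a in range(thinned.n_seq):
            for b in range(a + 1, thinned.n_seq):
                x, y = mat[a], mat[b]
                both = (x != GAP_CODE) & (y != GAP_CODE)
                denom = min((x != GAP_CODE).sum(), (y != GAP_CODE).sum())
                assert ((x == y) & both).sum() / denom <= 0.65

    def test_idempotent(self, random_msa):
        once = thin_msa(random_msa)
        twice = thin_msa(once)
        assert once.rows == twice.rows and once.ids == twice.ids


class TestBuildProfile:
    def test_conserved_column_zero_pseudocount(self):
        msa = Msa("s", ["s", "t"], ["AA", "AA"])
        prof = build_profile(msa, pseudocount_weight=0.0)
        assert prof.q[0, 0] == 1.0
        assert prof.t[0, 0] == pytest.approx(np.log2(1.0 / BACKGROUND[0]))

    def test_huge_pseudocount_limits_to_background(self, random_msa):
        prof = build_profile(random_msa, pseudocount_weight=1e14)
        assert np.allclose(prof.q, BACKGROUND, atol=1e-9)
        assert np.allclose(prof.t, 0.0, atol=1e-9)

    def test_matches_count_oracle(self, random_msa):
        w = 0.7
        prof = build_profile(random_msa, pseudocount_weight=w)
        mat = random_msa.matrix()
        for i in range(random_msa.n):
            col = [c for c in mat[:, i] if c != GAP_CODE]
            for a in range(20):
                q = (col.count(a) + w * BACKGROUND[a]) / (len(col) + w)
                assert prof.q[i, a] == pytest.approx(q, abs=1e-12)
                assert prof.t[i, a] == pytest.approx(np.log2(q / BACKGROUND[a]), abs=1e-10)

    def test_rows_sum_to_one(self, random_msa):
        prof = build_profile(random_msa, pseudocount_weight=0.3)
        assert np.allclose(prof.q.sum(axis=1), 1.0, atol=1e-9)


PSSM_HEADER = "           " + "  ".join(list("ARNDCQEGHILKMFPSTWYV") * 2)


class TestPsiblastPssm:
    def _write(self, path, rows):
        lines = ["", "Last position-specific scoring matrix computed", PSSM_HEADER]
        lines += rows
        lines += ["", "                      K         Lambda"]
        path.write_text("\n".join(lines))

    def test_scores_parsed_verbatim(self, tmp_path):
        scores = [list(range(-9, 11)), [1] * 20, list(range(20))]
        rows = []
        for k, sc in enumerate(scores, 1):
            rows.append(f"{k:5d} A " + " ".join(str(v) for v in sc)
                        + "  " + " ".join("5" for _ in range(20)))
        p = tmp_path / "x.pssm"
        self._write(p, rows)
        prof = read_psiblast_pssm(p)
        assert prof.n == 3
        # header order ARND... mapped into ALPHABET order
        order = "ARNDCQEGHILKMFPSTWYV"
        for k, sc in enumerate(scores):
            for col, aa in enumerate(order):
                assert prof.t[k, ALPHABET.index(aa)] == sc[col]

    def test_one_hot_percentages(self, tmp_path):
        row = ("    1 A " + " ".join("0" for _ in range(20))
               + "  100 " + " ".join("0" for _ in range(19)))
        p = tmp_path / "y.pssm"
        self._write(p, [row])
        prof = read_psiblast_pssm(p)
        assert prof.q[0, ALPHABET.index("A")] == 1.0
        assert prof.q[0].sum() == pytest.approx(1.0)

    def test_round_trip(self, tmp_path, rng):
        q = rng.random((5, 20))
        q /= q.sum(axis=1, keepdims=True)
        t = rng.normal(size=(5, 20)).round(4)
        prof = SequenceProfile(q=q, t=t)
        p = tmp_path / "rt.pssm"
        write_psiblast_pssm(prof, p)
        back = read_psiblast_pssm(p)
        assert np.allclose(back.q, prof.q, atol=1e-7)
        assert np.allclose(back.t, prof.t, atol=1e-9)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.pssm"
        self._write(p, ["    1 A 1 2 3"])
        with pytest.raises(FormatError):
            read_psiblast_pssm(p)


class TestSs2:
    def _write(self, path, rows):
        lines = ["# PSIPRED VFORMAT (PSIPRED V2.6)", ""]
        lines += [f"{k:4d} A {s} {c:6.3f} {h:6.3f} {e:6.3f}"
                  for k, (s, c, h, e) in enumerate(rows, 1)]
        path.write_text("\n".join(lines))

    def test_coil_argmax(self, tmp_path):
        p = tmp_path / "a.ss2"
        self._write(p, [("C", 0.9, 0.05, 0.05)])
        assert read_ss2(p).states == "C"

    def test_known_argmax_sequence(self, tmp_path):
        p = tmp_path / "b.ss2"
        rows = [("H", 0.1, 0.8, 0.1), ("H", 0.2, 0.7, 0.1), ("E", 0.1, 0.2, 0.7),
                ("C", 0.8, 0.1, 0.1), ("C", 0.5, 0.3, 0.2)]
        self._write(p, rows)
        assert read_ss2(p).states == "HHECC"

    def test_ties_resolved_h_over_e_over_c(self, tmp_path):
        p = tmp_path / "t.ss2"
        rows = [("?", 0.4, 0.4, 0.2),   # C==H -> H
                ("?", 0.2, 0.4, 0.4),   # H==E -> H
                ("?", 0.4, 0.2, 0.4),   # C==E -> E
                ("?", 1 / 3, 1 / 3, 1 / 3)]  # three-way -> H
        self._write(p, rows)
        assert read_ss2(p).states == "HHEH"
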