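"""The generator must be deterministic, honest about its noise models,
and plant features that are exactly recoverable at zero noise."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from cazymine import synthetic_data as sd
from cazymine.assay_analysis import fit_standard_curve, specific_activity
from cazymine.cazy_annotation import compute_bcr

from helpers_oracles import brute_force_orfs


class TestCommunity:
    def test_fixed_seed_is_byte_identical(self):
        a = sd.generate_community(n_taxa=5, n_genes=40, seed=7)
        b = sd.generate_community(n_taxa=5, n_genes=40, seed=7)
        assert a.genes == b.genes
        assert np.array_equal(a.abundance, b.abundance)
        assert a.taxa == b.taxa

    def test_abundances_on_simplex_and_genes_reference_taxa(self, community):
        assert math.isclose(float(community.abundance.sum()), 1.0, abs_tol=1e-9)
        assert all(0 <= g.taxon_index < len(community.taxa) for g in community.genes)
        assert all(g.orf_nt_length % 3 == 0 for g in community.genes)

    def test_degenerate_mix_labels_every_cazyme_gene_gh5(self):
        truth = sd.generate_community(n_genes=50, family_mix={"GH5": 1.0}, seed=3)
        fams = {g.cazy_family for g in truth.genes if g.cazy_family}
        assert fams == {"GH5"}

    def test_family_mix_within_multinomial_error(self):
        mix = {"GH3": 0.5, "GH5": 0.3, "GH9": 0.2}
        truth = sd.generate_community(
            n_genes=1000, family_mix=mix, non_cazyme_rate=0.0, seed=5
        )
        n = len(truth.genes)
        for fam, p in mix.items():
            observed = sum(g.cazy_family == fam for g in truth.genes)
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sigma

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_community(n_taxa=1)
        with pytest.raises(ValueError):
            sd.generate_community(n_genes=0)
        with pytest.raises(ValueError):
            sd.generate_community(family_mix={"GH5": 0.0})


class TestUnigenes:
    def test_zero_frag_fraction_keeps_every_orf_full_length(self, community, unigene_set):
        unigenes, table = unigene_set
        assert not table["truncated"].any()
        for row in table.itertuples():
            assert row.kept_nt == row.orf_nt_length
            seq = unigenes[row.unigene_id]
            orf = seq[row.orf_start : row.orf_end]
            assert len(orf) == row.orf_nt_length

    def test_reverse_strand_orf_found_only_in_reverse_frame(self, community, unigene_set):
        unigenes, table = unigene_set
        rev = table[table["strand"] == "-"].iloc[0]
        found = brute_force_orfs(unigenes[rev.unigene_id], min_len=int(rev.orf_nt_length))
        frames = {f for f, s, e in found if (s, e) == (rev.orf_start, rev.orf_end)}
        assert frames and frames <= {4, 5, 6}

    def test_flank_len_zero_means_unigene_equals_orf(self, community):
        unigenes, table = sd.generate_unigenes(community, flank_len=0, seed=2)
        for row in table.itertuples():
            assert len(unigenes[row.unigene_id]) == row.orf_nt_length

    def test_truncated_genes_carry_less_than_600_nt_of_orf(self, community):
        _, table = sd.generate_unigenes(community, frag_fraction=0.4, seed=9)
        trunc = table[table["truncated"]]
        assert len(trunc) == round(0.4 * len(table))
        assert (trunc["kept_nt"] < 600).all()

    def test_fasta_round_trip_parses_strictly(self, community, unigene_set, tmp_path):
        unigenes, _ = unigene_set
        path = tmp_path / "unigenes.fasta"
        sd.write_fasta(unigenes, path)
        parsed = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert parsed == unigenes

    def test_determinism(self, community):
        a = sd.generate_unigenes(community, seed=4)
        b = sd.generate_unigenes(community, seed=4)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])


class TestHitTable:
    def test_zero_noise_zero_decoys_all_rows_pass_all_filters(self, clean_hits):
        for hit in clean_hits:
            bcr_ref, bcr_que = compute_bcr(hit)
            assert hit.evalue <= 1e-5
            assert hit.bits > 60
            assert bcr_ref >= 40 and bcr_que >= 40

    def test_each_decoy_fails_exactly_its_named_filter(self, community, unigene_set):
        _, table = unigene_set
        hits = sd.generate_hit_table(community, table, decoy_rate=0.3, seed=21)
        decoys = [h for h in hits if h.query_id.startswith("DECOY_")]
        assert decoys
        for hit in decoys:
            kind = hit.query_id.split("_")[1]
            bcr_ref, bcr_que = compute_bcr(hit)
            failures = {
                "BCR": bcr_ref < 40 or bcr_que < 40,
                "BITS": hit.bits <= 60,
                "EVALUE": hit.evalue > 1e-5,
            }
            assert failures.pop(kind)
            assert not any(failures.values())

    def test_bits_monotone_in_alignment_length_at_fixed_identity(self, clean_hits):
        by_identity: dict[float, list] = {}
        for h in clean_hits:
            by_identity.setdefault(h.pct_identity, []).append(h)
        for group in by_identity.values():
            group.sort(key=lambda h: h.align_length)
            for a, b in zip(group, group[1:]):
                assert a.bits <= b.bits

    def test_determinism(self, community, unigene_set):
        _, table = unigene_set
        a = sd.generate_hit_table(community, table, seed=5)
        b = sd.generate_hit_table(community, table, seed=5)
        assert a == b


class TestCounts:
    def test_counts_are_nonnegative_integers_and_deterministic(self, unigene_set):
        _, table = unigene_set
        a = sd.generate_counts(table, seed=6)
        b = sd.generate_counts(table, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert (a.to_numpy() >= 0).all()
        assert np.issubdtype(a.to_numpy().dtype, np.integer)

    def test_column_sums_within_3_sigma_of_library_size(self, unigene_set):
        _, table = unigene_set
        lib = 100_000
        r = 0.5
        counts = sd.generate_counts(table, n_samples=4, library_size=lib, dispersion=r, seed=8)
        w = table["expression_rate"] * table["unigene_length"] / 1000.0
        mu = lib * w / w.sum()
        sigma = math.sqrt(float((mu + mu**2 / r).sum()))
        for col in counts:
            assert abs(counts[col].sum() - lib) <= 3 * sigma

    def test_nb_mean_recovered_over_replicates(self):
        table = pd.DataFrame(
            {
                "unigene_id": ["u1", "u2"],
                "unigene_length": [1000, 2000],
                "expression_rate": [2.0, 1.0],
            }
        )
        lib, r, reps = 10_000, 2.0, 200
        counts = sd.generate_counts(table, n_samples=reps, library_size=lib, dispersion=r, seed=10)
        w = table["expression_rate"] * table["unigene_length"] / 1000.0
        mu = (lib * w / w.sum()).to_numpy()
        for i in range(2):
            var = mu[i] + mu[i] ** 2 / r
            sem = math.sqrt(var / reps)
            assert abs(counts.iloc[i].mean() - mu[i]) <= 3 * sem

    def test_silenced_gene_has_all_zero_row_in_poisson_limit(self):
        table = pd.DataFrame(
            {
                "unigene_id": ["on", "off"],
                "unigene_length": [1000, 1000],
                "expression_rate": [1.0, 0.0],
            }
        )
        counts = sd.generate_counts(table, n_samples=20, dispersion=None, seed=1)
        assert (counts.loc["off"] == 0).all()
        assert counts.loc["on"].sum() > 0

    def test_invalid_dispersion_rejected(self, unigene_set):
        _, table = unigene_set
        with pytest.raises(ValueError):
            sd.generate_counts(table, dispersion=0.0)
        with pytest.raises(ValueError):
            sd.generate_counts(table, library_size=0)


class TestAssayPlate:
    def test_zero_noise_zero_activity_samples_equal_control_mean(self):
        plate = sd.generate_assay_plate([("e0", 0.0, "CMC")], noise_sd=0.0, seed=2)
        samples = plate[plate["role"] == "sample"]["absorbance"]
        controls = plate[plate["role"] == "control"]["absorbance"]
        assert samples.nunique() == 1
        assert samples.iloc[0] == pytest.approx(controls.mean())

    def test_planted_specific_activity_recovered_exactly_at_zero_noise(self):
        cfg = sd.AssayConfig()
        plate = sd.generate_assay_plate(
            [("cel", 222.2, "CMC")], curve_slope=0.5, curve_intercept=0.05,
            noise_sd=0.0, seed=3, config=cfg,
        )
        std = plate[plate["role"] == "standard"]
        curve = fit_standard_curve(std["concentration"].tolist(), std["absorbance"].tolist())
        a = plate[plate["role"] == "sample"]["absorbance"].mean()
        recovered = specific_activity(
            a, curve, cfg.reaction_minutes, cfg.reaction_volume_ml, cfg.protein_mg
        )
        assert recovered == pytest.approx(222.2, rel=0.02)

    def test_determinism_with_noise(self):
        a = sd.generate_assay_plate([("e", 10.0, "pNPC")], noise_sd=0.02, seed=4)
        b = sd.generate_assay_plate([("e", 10.0, "pNPC")], noise_sd=0.02, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_plate_arguments(self):
        with pytest.raises(ValueError):
            sd.generate_assay_plate([("e", 1.0, "CMC")], curve_slope=0.0)
        with pytest.raises(ValueError):
            sd.generate_assay_plate([("e", -1.0, "CMC")])
        with pytest.raises(ValueError):
            sd.generate_assay_plate([("e", 1.0, "CMC")], config=sd.AssayConfig(replicates=1))


class TestConfigAndClusters:
    def test_simulation_config_json_round_trip(self, tmp_path):
        cfg = sd.SimulationConfig(seed=42, frag_fraction=0.2)
        path = tmp_path / "config.json"
        cfg.to_json(path)
        assert sd.SimulationConfig.from_json(path) == cfg

    def test_protein_clusters_have_tight_within_and_wide_between_distances(self):
        seqs, truth = sd.generate_protein_clusters(n_clusters=3, per_cluster=3, seed=6)
        def ident(a, b):
            return sum(x == y for x, y in zip(a, b)) / len(a)
        for la in seqs:
            for lb in seqs:
                if la >= lb:
                    continue
                same = truth[la] == truth[lb] != "unclustered"
                if same:
                    assert ident(seqs[la], seqs[lb]) > 0.9
                else:
                    assert ident(seqs[la], seqs[lb]) < 0.5
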