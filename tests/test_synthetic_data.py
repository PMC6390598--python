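"""Simulator: panel determinism, truth-channel fidelity, error injection, IO."""

import math

import numpy as np
import pytest

from mbseq import (
    SimulationConfig,
    amplify_and_sequence,
    build_default_panel,
    inject_artifact,
    make_sample_profile,
    read_fastq_pairs,
    simulate_molecules,
    write_outputs,
)
from mbseq.synthetic_data import revcomp


class TestPanel:
    def test_default_panel_is_deterministic(self):
        a, b = build_default_panel(), build_default_panel()
        assert a.contig_sequence == b.contig_sequence
        assert a.amplicons == b.amplicons
        assert a.catalog == b.catalog

    def test_panel_has_seven_amplicons_with_valid_intervals(self, panel):
        assert len(panel.amplicons) == 7
        for amp in panel.amplicons:
            assert amp.end > amp.start
            assert set(amp.sequence) <= set("ACGT")
            assert amp.sequence == panel.contig_sequence[amp.start : amp.end]

    def test_catalog_covers_common_and_uncommon_hotspots(self, panel):
        assert {"L858R", "L861Q", "T790M", "exon19del", "G719A", "G719S", "G719C"} <= set(
            panel.catalog
        )
        assert {"G598V", "R776H", "D761Y", "E709G"} <= set(panel.catalog)

    def test_catalog_variants_match_reference_bases(self, panel):
        for label, v in panel.catalog.items():
            assert panel.contig_sequence[v.pos : v.pos + len(v.ref)] == v.ref
            assert v.ref != v.alt

    def test_exon19_deletion_is_left_aligned_anchor_form(self, panel):
        d = panel.catalog["exon19del"]
        assert len(d.ref) == 16 and len(d.alt) == 1
        assert d.ref[0] == d.alt
        # cannot shift left: last deleted base differs from the anchor
        assert d.ref[-1] != d.ref[0]

    def test_barcode_collisions_below_one_per_amplicon_at_defaults(self, panel):
        config = SimulationConfig()
        assert panel.expected_barcode_collisions(config) < 1.0


class TestSampleProfile:
    def test_profile_mirrors_af_pair_spec(self, panel):
        profile = make_sample_profile("p2294", [("L858R", 0.0656), ("G598V", 0.068)], panel)
        by_label = {v.label: f for v, f in profile.truth}
        assert by_label == {"L858R": 0.0656, "G598V": 0.068}

    def test_empty_profile_is_wild_type(self, panel):
        assert make_sample_profile("wt", [], panel).truth == ()

    @pytest.mark.parametrize(
        "spec", [[("L858R", 1.5)], [("L858R", 0.0)], [("NOT_A_HOTSPOT", 0.1)]]
    )
    def test_bad_profile_specs_raise(self, panel, spec):
        with pytest.raises(ValueError):
            make_sample_profile("bad", spec, panel)


class TestSimulateMolecules:
    def test_variant_molecule_count_within_binomial_band(self, panel):
        amp = panel.subset(["EGFR_ex21"])
        profile = make_sample_profile("s", [("L858R", 0.5)], amp)
        config = SimulationConfig(molecules_per_amplicon=10_000, seed=3)
        molecules = simulate_molecules(profile, config, amp)
        carriers = sum(bool(m.variants) for m in molecules)
        sd = math.sqrt(10_000 * 0.5 * 0.5)
        assert abs(carriers - 5_000) <= 3 * sd

    def test_fraction_one_hits_every_molecule(self, small_panel):
        profile = make_sample_profile("s", [("T790M", 1.0)], small_panel)
        config = SimulationConfig(molecules_per_amplicon=50, seed=1)
        t790m_pos = small_panel.catalog["T790M"].pos
        for m in simulate_molecules(profile, config, small_panel):
            if m.amplicon == "EGFR_ex20":
                assert any(k[1] == t790m_pos for k in m.variants)

    def test_same_seed_gives_identical_molecules(self, small_panel, l858r_profile):
        config = SimulationConfig(molecules_per_amplicon=30, seed=9)
        assert simulate_molecules(l858r_profile, config, small_panel) == simulate_molecules(
            l858r_profile, config, small_panel
        )

    def test_haplotype_carries_the_variant_base(self, small_panel):
        profile = make_sample_profile("s", [("L858R", 1.0)], small_panel)
        config = SimulationConfig(molecules_per_amplicon=5, seed=2)
        v = small_panel.catalog["L858R"]
        amp = small_panel.amplicon("EGFR_ex21")
        for m in simulate_molecules(profile, config, small_panel):
            if m.amplicon == "EGFR_ex21":
                assert m.haplotype[v.pos - amp.start] == v.alt


class TestAmplifyAndSequence:
    def test_error_free_reads_are_haplotype_substrings(self, small_panel, clean_config):
        profile = make_sample_profile("s", [("L858R", 0.5)], small_panel)
        molecules = simulate_molecules(profile, clean_config, small_panel)
        by_id = {m.molecule_id: m for m in molecules}
        reads = amplify_and_sequence(molecules, clean_config)
        assert reads
        for pair in reads:
            hap = by_id[pair.origin].haplotype
            assert pair.mate1 == hap[: clean_config.read_length]
            assert revcomp(pair.mate2) == hap[-clean_config.read_length :]

    def test_sequencing_error_count_within_binomial_band(self, small_panel):
        config = SimulationConfig(
            molecules_per_amplicon=2500,
            reads_per_molecule=(2.0, 0.0),
            pcr_error_rate=0.0,
            seq_error_rate=0.01,
            seed=4,
        )
        profile = make_sample_profile("wt", [], small_panel.subset(["EGFR_ex21"]))
        molecules = simulate_molecules(profile, config, small_panel.subset(["EGFR_ex21"]))
        reads = amplify_and_sequence(molecules, config)
        by_id = {m.molecule_id: m for m in molecules}
        mismatches = bases = 0
        for pair in reads:
            hap = by_id[pair.origin].haplotype
            for got, want in (
                (pair.mate1, hap[: config.read_length]),
                (revcomp(pair.mate2), hap[-config.read_length :]),
            ):
                mismatches += sum(a != b for a, b in zip(got, want))
                bases += len(got)
        sd = math.sqrt(bases * 0.01 * 0.99)
        assert abs(mismatches - bases * 0.01) <= 3 * sd

    def test_mean_family_size_matches_distribution(self, small_panel):
        config = SimulationConfig(
            molecules_per_amplicon=2000, reads_per_molecule=(5.0, 1.0), seed=6
        )
        profile = make_sample_profile("wt", [], small_panel)
        molecules = simulate_molecules(profile, config, small_panel)
        reads = amplify_and_sequence(molecules, config)
        mean = len(reads) / len(molecules)
        sd = math.sqrt(5.0 / len(molecules))  # SE of a Poisson mean
        assert abs(mean - 5.0) <= 3 * sd

    def test_barcodes_copied_without_error_by_default(self, small_panel, clean_config):
        profile = make_sample_profile("wt", [], small_panel)
        molecules = simulate_molecules(profile, clean_config, small_panel)
        by_id = {m.molecule_id: m for m in molecules}
        for pair in amplify_and_sequence(molecules, clean_config):
            assert pair.barcode == by_id[pair.origin].barcode


class TestInjectArtifact:
    def _cohort(self, small_panel, n, seed=0):
        profile = make_sample_profile("wt", [], small_panel)
        cohort = []
        for i in range(n):
            config = SimulationConfig(
                molecules_per_amplicon=30, reads_per_molecule=(2.0, 0.0),
                pcr_error_rate=0.0, seq_error_rate=0.0, seed=seed + i,
            )
            molecules = simulate_molecules(profile, config, small_panel)
            cohort.append(amplify_and_sequence(molecules, config))
        return cohort

    def _samples_with_artifact(self, samples, site, small_panel):
        amp = small_panel.amplicon_at(site.contig, site.pos)
        offset = site.pos - amp.start
        hit = []
        for reads in samples:
            found = any(
                p.mate1[offset] == site.alt and p.read_id.startswith("artifact")
                for p in reads
                if len(p.mate1) > offset
            )
            hit.append(found)
        return hit

    def test_systematic_artifact_lands_in_more_than_half(self, small_panel):
        samples = self._cohort(small_panel, 28)
        site = small_panel.catalog["R776H"]
        config = SimulationConfig(seed=0)
        out = inject_artifact(samples, site, "systematic", 0.05, small_panel, config)
        assert sum(self._samples_with_artifact(out, site, small_panel)) >= 15

    def test_singleton_artifact_lands_in_exactly_one(self, small_panel):
        samples = self._cohort(small_panel, 8)
        site = small_panel.catalog["T790M"]
        config = SimulationConfig(seed=0)
        out = inject_artifact(samples, site, "singleton", 0.05, small_panel, config)
        assert sum(self._samples_with_artifact(out, site, small_panel)) == 1

    def test_injected_reads_have_fresh_singleton_barcodes(self, small_panel):
        samples = self._cohort(small_panel, 4)
        site = small_panel.catalog["T790M"]
        config = SimulationConfig(seed=0)
        out = inject_artifact(samples, site, "singleton", 0.1, small_panel, config)
        for before, after in zip(samples, out):
            injected = after[len(before):]
            existing = {p.barcode for p in before}
            barcodes = [p.barcode for p in injected]
            assert len(barcodes) == len(set(barcodes))  # family size 1 each
            assert not (set(barcodes) & existing)

    def test_rate_zero_returns_input_unchanged(self, small_panel):
        samples = self._cohort(small_panel, 3)
        site = small_panel.catalog["T790M"]
        out = inject_artifact(samples, site, "systematic", 0.0, small_panel, SimulationConfig())
        assert out is samples

    def test_negative_rate_and_small_cohorts_raise(self, small_panel):
        samples = self._cohort(small_panel, 2)
        site = small_panel.catalog["T790M"]
        with pytest.raises(ValueError):
            inject_artifact(samples, site, "systematic", -0.1, small_panel, SimulationConfig())
        with pytest.raises(ValueError):
            inject_artifact(samples, site, "systematic", 0.1, small_panel, SimulationConfig())


class TestOutputs:
    def test_round_trip_preserves_reads_and_formats(self, tmp_path, small_panel, clean_config):
        profile = make_sample_profile("s1", [("L858R", 0.2)], small_panel)
        molecules = simulate_molecules(profile, clean_config, small_panel)
        reads = amplify_and_sequence(molecules, clean_config)
        paths = write_outputs(reads, small_panel, profile, tmp_path)

        back = read_fastq_pairs(paths["fastq1"], paths["fastq2"])
        assert len(back) == len(reads)
        assert [(p.read_id, p.barcode, p.mate1, p.mate2) for p in back] == [
            (p.read_id, p.barcode, p.mate1, p.mate2) for p in reads
        ]

        fq = paths["fastq1"].read_text().splitlines()
        assert len(fq) == 4 * len(reads)
        for i in range(0, len(fq), 4):
            assert fq[i].startswith("@") and fq[i + 2] == "+"
            assert len(fq[i + 1]) == len(fq[i + 3])

        bed_rows = [line.split("\t") for line in paths["bed"].read_text().splitlines()]
        assert [(r[3], int(r[1]), int(r[2])) for r in bed_rows] == [
            (a.name, a.start, a.end) for a in small_panel.amplicons
        ]

        truth = paths["truth"].read_text().splitlines()
        assert truth[0].startswith("sample_id\t")
        assert len(truth) == 1 + len(profile.truth)

    def test_same_seed_gives_byte_identical_fastq(self, tmp_path, small_panel, l858r_profile):
        config = SimulationConfig(molecules_per_amplicon=40, seed=13)
        for sub in ("a", "b"):
            molecules = simulate_molecules(l858r_profile, config, small_panel)
            reads = amplify_and_sequence(molecules, config)
            write_outputs(reads, small_panel, l858r_profile, tmp_path / sub)
        assert (tmp_path / "a" / "s1_R1.fastq").read_bytes() == (
            tmp_path / "b" / "s1_R1.fastq"
        ).read_bytes()

    def test_barcode_fastq_dialect_round_trip(self, tmp_path, small_panel, clean_config):
        profile = make_sample_profile("s1", [], small_panel)
        molecules = simulate_molecules(profile, clean_config, small_panel)
        reads = amplify_and_sequence(molecules, clean_config)[:10]
        paths = write_outputs(reads, small_panel, profile, tmp_path)
        # synthesise the index-read dialect from the name-suffix dialect
        index = tmp_path / "index.fastq"
        with open(index, "w") as out:
            for p in reads:
                out.write(f"@{p.read_id}\n{p.barcode}\n+\n{'?' * len(p.barcode)}\n")
        # strip suffixes from R1/R2 names
        for key in ("fastq1", "fastq2"):
            lines = paths[key].read_text().splitlines()
            with open(paths[key], "w") as out:
                for i, line in enumerate(lines[: 4 * len(reads)]):
                    out.write(line.rsplit(":", 1)[0] + "\n" if i % 4 == 0 else line + "\n")
        back = read_fastq_pairs(paths["fastq1"], paths["fastq2"], barcode_fastq=index)
        assert [p.barcode for p in back] == [p.barcode for p in reads]

    def test_config_file_round_trip(self, tmp_path):
        config = SimulationConfig(molecules_per_amplicon=123, seq_error_rate=0.01, seed=7)
        path = tmp_path / "sim.cfg"
        config.to_file(path)
        assert SimulationConfig.from_file(path) == config
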