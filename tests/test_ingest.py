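"""VCF ingest, QC/AF filtering, consequence selection and table joins."""
import itertools

import pandas as pd
import pytest

from evidenceyield.ingest import (
    AnnotationSpec,
    FilterConfig,
    ScoreTable,
    apply_af_filter,
    apply_genotype_filters,
    ingest_cohort,
    join_genes,
    join_scores,
    load_cohort_vcf,
    load_gene_table,
    select_missense,
)
from evidenceyield.types import (
    ConfigurationError,
    ConsequenceAnnotation,
    DataError,
    FrequencyRecord,
    GeneRecord,
    GenotypeQC,
    VariantKey,
    VariantObservation,
    compute_popmax,
)


def make_obs(gq=50, dp=30, ab=0.5, global_af=0.0, pops=None, annotations=None, zyg="het"):
    return VariantObservation(
        proband_id="P1",
        key=VariantKey("chr1", 100, "A", "G"),
        qc=GenotypeQC(genotype_quality=gq, depth=dp, allele_balance=ab, zygosity=zyg),
        freq=FrequencyRecord(global_af=global_af, per_population_af=pops or {}),
        annotations=annotations or [ConsequenceAnnotation("ENST1", "GENEA", "missense_variant", True)],
    )


class TestVcfReading:
    def test_observations_and_decomposition(self, handmade_vcf):
        obs = list(load_cohort_vcf(handmade_vcf, "S1"))
        # 7 lines; the 1/2 multi-allelic line contributes two records
        assert len(obs) == 8
        by_pos = {}
        for o in obs:
            by_pos.setdefault(o.key.pos, []).append(o)
        assert len(by_pos[200]) == 2
        assert {o.key.alt for o in by_pos[200]} == {"G", "T"}
        assert all(o.key.ref == "A" and o.key.chrom == "chr1" for o in by_pos[200])

    def test_allele_balance_is_alt_reads_over_depth(self, handmade_vcf):
        obs = {o.key.pos: o for o in load_cohort_vcf(handmade_vcf, "S1")
               if o.key.pos in (100, 600)}
        assert obs[100].qc.allele_balance == pytest.approx(0.7)  # AD=3,7 DP=10
        assert obs[100].qc.zygosity == "het"
        assert obs[600].qc.zygosity == "hom_alt"

    def test_missing_qc_subfields_flagged_absent_not_zero(self, handmade_vcf):
        obs = {o.key.pos: o for o in load_cohort_vcf(handmade_vcf, "S1")}
        assert obs[300].qc.genotype_quality is None
        assert obs[300].qc.depth == 12

    def test_per_alt_allele_frequencies(self, handmade_vcf):
        by = {(o.key.pos, o.key.alt): o for o in load_cohort_vcf(handmade_vcf, "S1")}
        assert by[(200, "G")].freq.global_af == pytest.approx(0.001)
        assert by[(200, "T")].freq.global_af == pytest.approx(0.002)
        assert by[(400, "A")].freq.global_af == 0.0  # absent from resource -> novel
        assert by[(100, "G")].freq.per_population_af["nfe"] == pytest.approx(0.002)

    def test_empty_vcf_yields_empty_stream(self, tmp_path, handmade_vcf):
        header = "\n".join(line for line in open(handmade_vcf).read().splitlines()
                           if line.startswith("#")) + "\n"
        path = tmp_path / "empty.vcf"
        path.write_text(header)
        assert list(load_cohort_vcf(str(path), "S1")) == []

    def test_malformed_vcf_raises_data_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises((DataError, ValueError)):
            list(load_cohort_vcf(str(path), "S1"))

    def test_annotation_spec_mismatch_is_configuration_error(self, handmade_vcf):
        spec = AnnotationSpec(mane_field="MANE_PLUS_CLINICAL")
        with pytest.raises(ConfigurationError, match="MANE_PLUS_CLINICAL"):
            list(load_cohort_vcf(handmade_vcf, "S1", spec))


class TestGenotypeFilters:
    @pytest.mark.parametrize("gq,dp,ab,keep,reason", [
        (39, 50, 0.5, False, "genotype_quality"),  # 39 fails the >= 40 bound
        (40, 10, 0.2, True, None),                 # boundary values satisfy >=
        (99, 9, 0.5, False, "depth"),
        (99, 50, 0.19, False, "allele_balance"),
        (None, 50, 0.5, False, "missing_qc"),
        (50, None, 0.5, False, "missing_qc"),
        (50, 50, None, False, "missing_qc"),
    ])
    def test_bounds_and_first_failing_reason(self, gq, dp, ab, keep, reason):
        got_keep, got_reason = apply_genotype_filters(make_obs(gq=gq, dp=dp, ab=ab))
        assert (got_keep, got_reason) == (keep, reason)

    def test_thresholds_configurable(self):
        cfg = FilterConfig(gq_min=20)
        assert apply_genotype_filters(make_obs(gq=25), cfg) == (True, None)


class TestPopmaxAndAf:
    def test_popmax_excludes_bottlenecked_populations(self):
        afs = {"afr": 0.02, "nfe": 0.001, "fin": 0.20}
        assert compute_popmax(afs, {"fin"}) == pytest.approx(0.02)

    def test_popmax_all_excluded_is_zero(self):
        assert compute_popmax({"fin": 0.20}, {"fin"}) == 0.0
        assert compute_popmax({}) == 0.0
        assert compute_popmax({"nfe": 0.0}) == 0.0

    def test_af_outside_unit_interval_is_data_error(self):
        with pytest.raises(DataError):
            compute_popmax({"nfe": 1.5})

    @pytest.mark.parametrize("global_af,pops,max_af,keep", [
        (0.005, {"afr": 0.012}, 0.01, False),  # both bounds must hold
        (0.01, {"afr": 0.01}, 0.01, True),     # boundary satisfies <=
        (0.0, {}, 0.0001, True),               # novel variants kept at any threshold
        (0.02, {}, 0.01, False),
    ])
    def test_af_filter(self, global_af, pops, max_af, keep):
        obs = make_obs(global_af=global_af, pops=pops)
        got, reason = apply_af_filter(obs, max_af)
        assert got is keep
        assert reason == (None if keep else "allele_frequency")

    def test_bottlenecked_population_does_not_trigger_af_drop(self, handmade_vcf):
        obs = {o.key.pos: o for o in load_cohort_vcf(handmade_vcf, "S1")}
        keep, _ = apply_af_filter(obs[700], 0.01)  # AF_fin=0.2 but fin is excluded
        assert keep


class TestSelectMissense:
    MANE_SYN = [ConsequenceAnnotation("ENST02", "GENEB", "synonymous_variant", True),
                ConsequenceAnnotation("ENST03", "GENEB", "missense_variant", False)]

    def test_mane_mode_requires_missense_on_mane_transcript(self):
        obs = make_obs(annotations=self.MANE_SYN)
        selected, reason = select_missense(obs, "mane_select")
        assert selected is None and reason == "not_missense"

    def test_most_severe_mode_rescues_alternative_transcript_missense(self):
        obs = make_obs(annotations=self.MANE_SYN)
        selected, reason = select_missense(obs, "most_severe")
        assert reason is None
        assert selected.selected_annotation.transcript_id == "ENST03"

    def test_mane_missense_selected(self):
        obs = make_obs()
        selected, _ = select_missense(obs, "mane_select")
        assert selected.selected_annotation.is_mane_select

    def test_no_mane_transcript_reason(self):
        obs = make_obs(annotations=[
            ConsequenceAnnotation("ENST04", "GENEC", "missense_variant", False)])
        assert select_missense(obs, "mane_select") == (None, "no_mane_transcript")

    def test_most_severe_drops_when_truncating_consequence_dominates(self):
        obs = make_obs(annotations=[
            ConsequenceAnnotation("ENST05", "GENED", "stop_gained", True),
            ConsequenceAnnotation("ENST06", "GENED", "missense_variant", False)])
        assert select_missense(obs, "most_severe") == (None, "not_missense")

    def test_most_severe_prefers_mane_on_ties(self):
        obs = make_obs(annotations=[
            ConsequenceAnnotation("ENST_ALT", "GENEA", "missense_variant", False),
            ConsequenceAnnotation("ENST_MANE", "GENEA", "missense_variant", True)])
        selected, _ = select_missense(obs, "most_severe")
        assert selected.selected_annotation.transcript_id == "ENST_MANE"

    def test_ampersand_joined_terms_are_split(self):
        obs = make_obs(annotations=[ConsequenceAnnotation(
            "ENST1", "GENEA", "missense_variant&splice_region_variant", True)])
        selected, _ = select_missense(obs, "mane_select")
        assert selected is not None


class TestJoins:
    FRAME = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "pos": [100, 100], "ref": ["A", "A"],
        "alt": ["G", "G"], "transcript": ["ENST1", "ENST_OTHER"],
        "BayesDel_noAF": [0.3, None], "MutPred2": [None, None],
        "REVEL": [None, 0.9], "VEST4": [0.5, None],
    })

    def test_transcript_specific_scores_follow_selected_transcript(self):
        table = ScoreTable(self.FRAME)
        obs, _ = select_missense(make_obs(), "mane_select")
        join_scores(obs, table)
        assert obs.scores["VEST4"] == 0.5
        assert obs.scores["REVEL"] is None  # present only on a non-selected transcript
        assert obs.scores["BayesDel_noAF"] == 0.3  # variant-keyed, transcript ignored

    def test_variant_absent_from_table_all_missing(self):
        table = ScoreTable(self.FRAME)
        obs = make_obs()
        obs.key = VariantKey("chr9", 999, "A", "G")
        obs, _ = select_missense(obs, "mane_select")
        join_scores(obs, table)
        assert all(v is None for v in obs.scores.values())

    def test_conflicting_duplicate_scores_rejected(self):
        frame = pd.concat([self.FRAME, self.FRAME.assign(BayesDel_noAF=[0.4, None])])
        with pytest.raises(DataError, match="conflicting"):
            ScoreTable(frame)

    def test_gene_scope(self):
        genes = {"GENEA": GeneRecord("GENEA", "Moderate", "AR_only")}
        obs, _ = select_missense(make_obs(), "mane_select")
        keep, reason = join_genes(obs, genes, "disease_genes")
        assert keep and obs.gene.moi == "AR_only"
        obs2, _ = select_missense(make_obs(annotations=[
            ConsequenceAnnotation("ENSTX", "UNLISTED", "missense_variant", True)]), "mane_select")
        assert join_genes(obs2, genes, "disease_genes") == (False, "gene_scope")
        assert join_genes(obs2, genes, "genome_wide") == (True, None)
        assert obs2.gene is None

    def test_gene_table_loader_rejects_duplicates(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("symbol\tvalidity\tmoi\nG1\tStrong\tAD_only\nG1\tStrong\tAD_only\n")
        with pytest.raises(DataError, match="duplicate"):
            load_gene_table(str(path))


class TestChain:
    def brute_force_filter(self, vcfs, gene_table, max_af):
        """Independent single-pass re-implementation of the whole chain."""
        kept = []
        excluded = {"asj", "fin", "ami", "mid", "oth"}
        for pid, path in vcfs.items():
            for obs in load_cohort_vcf(path, pid):
                mane = [a for a in obs.annotations
                        if a.is_mane_select and "missense_variant" in a.consequence.split("&")]
                if not mane:
                    continue
                qc = obs.qc
                if qc.genotype_quality is None or qc.depth is None or qc.allele_balance is None:
                    continue
                if qc.genotype_quality < 40 or qc.depth < 10 or qc.allele_balance < 0.2:
                    continue
                pops = [af for pop, af in obs.freq.per_population_af.items()
                        if pop not in excluded]
                if obs.freq.global_af > max_af or (pops and max(pops) > max_af):
                    continue
                record = gene_table.get(mane[0].gene_symbol)
                if record is None or record.validity not in ("Definitive", "Strong", "Moderate"):
                    continue
                kept.append((pid, obs.key.chrom, obs.key.pos, obs.key.ref, obs.key.alt))
        return sorted(kept)

    @pytest.fixture()
    def two_proband_vcfs(self, small_fixtures):
        items = sorted(small_fixtures["vcfs"].items())[:2]
        return {pid: str(path) for pid, path in items}

    def test_chain_matches_brute_force_oracle(self, small_fixtures, two_proband_vcfs):
        gene_table = load_gene_table(str(small_fixtures["genes"]))
        result = ingest_cohort(two_proband_vcfs, None, gene_table, FilterConfig())
        got = sorted(map(tuple, result.observations[
            ["proband_id", "chrom", "pos", "ref", "alt"]].to_numpy()))
        assert got == self.brute_force_filter(two_proband_vcfs, gene_table, 0.01)

    def test_af_threshold_monotone_kept_sets(self, small_fixtures, two_proband_vcfs):
        gene_table = load_gene_table(str(small_fixtures["genes"]))
        kept = {}
        for max_af in (0.01, 0.05):
            result = ingest_cohort(two_proband_vcfs, None, gene_table,
                                   FilterConfig(max_af=max_af))
            kept[max_af] = set(map(tuple, result.observations[
                ["proband_id", "chrom", "pos", "ref", "alt"]].to_numpy()))
        assert kept[0.01] <= kept[0.05]

    def test_count_bookkeeping_exact_per_proband(self, small_fixtures):
        vcfs = {pid: str(path) for pid, path in small_fixtures["vcfs"].items()}
        gene_table = load_gene_table(str(small_fixtures["genes"]))
        result = ingest_cohort(vcfs, None, gene_table, FilterConfig())
        kept = result.kept_per_proband()
        dropped = result.drop_counts.groupby("proband_id")["count"].sum()
        for pid, n_raw in result.raw_counts.items():
            assert n_raw == kept.get(pid, 0) + dropped.get(pid, 0)

    def test_engineered_failures_drop_with_engineered_reasons(self, small_cohort, small_fixtures):
        vcfs = {pid: str(path) for pid, path in small_fixtures["vcfs"].items()}
        gene_table = load_gene_table(str(small_fixtures["genes"]))
        result = ingest_cohort(vcfs, None, gene_table, FilterConfig())
        got = result.drop_counts.groupby("reason")["count"].sum().to_dict()
        expected = small_cohort.truth["expected_drop_reason"].value_counts().to_dict()
        assert got == expected
        assert len(result.observations) == small_cohort.truth["expected_drop_reason"].isna().sum()
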