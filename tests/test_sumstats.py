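"""Summary-statistics IO, allele orientation and curation filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pleioaudit.sumstats import (
    AlleleMismatchError,
    AssocStat,
    CANONICAL_DIALECT,
    Dialect,
    MissingMetadataError,
    PhenotypeMeta,
    SumstatsFormatError,
    VariantKey,
    filter_curated,
    orient_to_target_allele,
    read_phenotype_manifest,
    read_sumstats,
    write_phenotype_manifest,
    write_sumstats,
)

VARIANT = VariantKey(chrom="3", pos=46414943, ref="TACAGTCAGTATCAATTCTGGAAGAATTTCCAG", alt="T")


def make_assoc(phenotype_id="D001", beta=0.1, eaf=0.9, effect_allele="T", se=0.05, p=0.04, n=1000):
    return AssocStat(
        variant=VARIANT,
        phenotype_id=phenotype_id,
        effect_allele=effect_allele,
        eaf=eaf,
        n=n,
        beta_obs=beta,
        se_obs=se,
        p=p,
    )


alleles = st.text(alphabet="ACGT", min_size=1, max_size=8)


@given(
    chrom=st.sampled_from([str(c) for c in range(1, 23)] + ["X"]),
    pos=st.integers(min_value=1, max_value=3_000_000_000),
    ref=alleles,
    alt=alleles,
)
def test_variant_id_roundtrip(chrom, pos, ref, alt):
    """chrom:pos_ref_alt formatting and parsing are mutually inverse."""
    if ref == alt:
        with pytest.raises(ValueError):
            VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)
        return
    v = VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)
    assert VariantKey.parse(v.id) == v


def test_variant_validation():
    with pytest.raises(ValueError):
        VariantKey(chrom="1", pos=0, ref="A", alt="T")
    with pytest.raises(SumstatsFormatError):
        VariantKey.parse("not-a-variant")


class TestReadWrite:
    def test_well_formed_file_roundtrip(self, tmp_path):
        records = [make_assoc(f"D{i:03d}", beta=0.01 * i - 0.01) for i in range(1, 4)]
        path = tmp_path / "ss.tsv"
        write_sumstats(records, path)
        back = read_sumstats(path)
        assert back == records

    def test_na_rows_skipped_and_logged(self, tmp_path, caplog):
        path = tmp_path / "ss.tsv"
        header = "variant\tphenotype\teffect_allele\teaf\tn\tbeta\tse\tpval\n"
        rows = [
            f"{VARIANT.id}\tD001\tT\t0.9\t100\t0.1\t0.05\t0.04\n",
            f"{VARIANT.id}\tD002\tT\t0.9\t100\tNA\t0.05\t0.04\n",
            f"{VARIANT.id}\tD003\tT\t0.9\t100\t-0.2\t0.05\t0.01\n",
        ]
        path.write_text(header + "".join(rows))
        with caplog.at_level("INFO"):
            records = read_sumstats(path)
        assert len(records) == 2
        assert {r.phenotype_id for r in records} == {"D001", "D003"}
        assert "skipped 1" in caplog.text

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("variant\tphenotype\teffect_allele\teaf\tn\tbeta\tse\n" + "x\ty\tT\t0.1\t10\t0\t1\n")
        with pytest.raises(SumstatsFormatError, match="pval"):
            read_sumstats(path)

    def test_bad_frequency_collected(self, tmp_path):
        path = tmp_path / "ss.tsv"
        header = "variant\tphenotype\teffect_allele\teaf\tn\tbeta\tse\tpval\n"
        path.write_text(header + f"{VARIANT.id}\tD001\tT\t1.7\t100\t0.1\t0.05\t0.04\n")
        with pytest.raises(SumstatsFormatError, match="frequency"):
            read_sumstats(path)

    def test_per_phenotype_dialect_without_column(self, tmp_path):
        d = Dialect(phenotype=None)
        path = tmp_path / "ss.tsv"
        header = "variant\teffect_allele\teaf\tn\tbeta\tse\tpval\n"
        path.write_text(header + f"{VARIANT.id}\tT\t0.9\t100\t0.1\t0.05\t0.04\n")
        with pytest.raises(SumstatsFormatError):
            read_sumstats(path, dialect=d)
        (rec,) = read_sumstats(path, dialect=d, phenotype_id="D042")
        assert rec.phenotype_id == "D042"

    def test_manifest_roundtrip(self, tmp_path):
        metas = [PhenotypeMeta("D001", "gout", 1200, 300000), PhenotypeMeta("D002", "asthma", 35000, 320000)]
        path = tmp_path / "manifest.tsv"
        write_phenotype_manifest(metas, path)
        assert read_phenotype_manifest(path) == metas


class TestOrientation:
    def test_identity_when_target_matches(self):
        a = make_assoc()
        assert orient_to_target_allele(a, "T") is a

    def test_flip_negates_beta_and_complements_eaf(self):
        a = make_assoc(beta=0.1, eaf=0.9, effect_allele="T")
        b = orient_to_target_allele(a, VARIANT.ref)
        assert b.beta_obs == -0.1
        assert b.eaf == pytest.approx(0.1)
        assert b.effect_allele == VARIANT.ref
        assert (b.se_obs, b.p, b.n) == (a.se_obs, a.p, a.n)

    def test_mismatched_allele_raises(self):
        with pytest.raises(AlleleMismatchError):
            orient_to_target_allele(make_assoc(), "G")

    @given(
        beta=st.floats(-0.5, 0.5, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        start=st.sampled_from(["T", "TACAGTCAGTATCAATTCTGGAAGAATTTCCAG"]),
    )
    def test_involution(self, beta, eaf, start):
        """Orienting to the other allele twice restores the original record."""
        a = make_assoc(beta=beta, eaf=eaf, effect_allele=start)
        other = VARIANT.ref if start == VARIANT.alt else VARIANT.alt
        b = orient_to_target_allele(a, other)
        assert abs(b.beta_obs) == abs(a.beta_obs)
        assert (b.se_obs, b.p, b.n) == (a.se_obs, a.p, a.n)
        back = orient_to_target_allele(b, start)
        assert back.beta_obs == a.beta_obs  # negation is exact
        assert back.eaf == pytest.approx(a.eaf, abs=1e-15)  # complement is not
        assert back.effect_allele == a.effect_allele


class TestFilterCurated:
    @pytest.fixture()
    def panel(self):
        metas = [
            PhenotypeMeta("A", "a", 999, 1000),
            PhenotypeMeta("B", "b", 1000, 1000),
            PhenotypeMeta("C", "c", 5000, 1000),
        ]
        assocs = [make_assoc(pid) for pid in "ABC"]
        return assocs, metas

    def test_boundary_is_inclusive(self, panel):
        assocs, metas = panel
        kept = filter_curated(assocs, metas, min_cases=1000)
        assert [a.phenotype_id for a in kept] == ["B", "C"]

    def test_zero_threshold_keeps_all(self, panel):
        assocs, metas = panel
        assert filter_curated(assocs, metas, min_cases=0) == assocs

    def test_missing_metadata_raises(self, panel):
        assocs, metas = panel
        with pytest.raises(MissingMetadataError, match="A"):
            filter_curated(assocs, metas[1:])

    def test_matches_bruteforce_and_monotone(self, default_panel):
        assocs, metas, _ = default_panel
        by_id = {m.phenotype_id: m for m in metas}
        sizes = []
        for min_cases in [0, 1000, 5000, 20000, 10**7]:
            kept = filter_curated(assocs, metas, min_cases=min_cases)
            expected = [a for a in assocs if by_id[a.phenotype_id].n_cases >= min_cases]
            assert kept == expected
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)
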