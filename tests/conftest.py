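import pandas as pd
import pytest

from streamtherm.io import CommunityDataset, SampleRecord, SegmentTemperature, TaxonNode
from streamtherm.synthetic import DEFAULT_SCENARIO, generate_dataset


@pytest.fixture(scope="session")
def default_scenario_data():
    """Default synthetic scenario: (dataset, truth table, otu_map)."""
    return generate_dataset(DEFAULT_SCENARIO)


@pytest.fixture(scope="session")
def prepped(default_scenario_data):
    import streamtherm as st

    dataset, truth, otu_map = default_scenario_data
    prep = st.prepare(dataset)
    return dataset, truth, otu_map, prep


@pytest.fixture
def toy_csvs(tmp_path):
    """Minimal 3-taxon, 2-sample CSV trio."""
    (tmp_path / "counts.csv").write_text(
        "sample_id,taxon_id,count\n"
        "s1,tA,10\ns1,tB,5\ns2,tB,3\ns2,tC,7\n"
    )
    (tmp_path / "taxonomy.csv").write_text(
        "taxon_id,name,parent_id,rank\n"
        "tA,Alpha,,genus\ntB,Beta,,genus\ntC,Gamma,tB_fam,genus\ntB_fam,Betidae,,family\n"
    )
    (tmp_path / "sites.csv").write_text(
        "sample_id,site_id,segment_id,unit,year,mwmt_2010,mwmt_mean,mean_august\n"
        "s1,siteX,seg1,U1,2010,18.2,17.5,15.0\n"
        "s2,siteY,seg2,U1,2012,,15.0,13.0\n"
    )
    return tmp_path


def make_sample(sample_id, counts, segment_id="seg", year=2010, unit="U", site_id="site"):
    return SampleRecord(
        sample_id=sample_id, site_id=site_id, segment_id=segment_id,
        unit=unit, year=year, counts=counts,
    )


def make_flat_taxa(ids, rank="genus"):
    return {t: TaxonNode(t, t.upper(), None, rank) for t in ids}


@pytest.fixture
def flat_dataset():
    """Five independent genera, one segment, no hierarchy."""
    taxa = make_flat_taxa(["t1", "t2", "t3", "t4", "t5"])
    temps = {"seg": SegmentTemperature("seg", annual_mwmt={2010: 15.0})}
    return CommunityDataset(taxa=taxa, samples=[], temperatures=temps)
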