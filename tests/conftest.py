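import numpy as np
import pytest

from clonaltrack import Clonotype, RepertoireSample, Timepoint
from clonaltrack.simulate import SimulationParams


@pytest.fixture
def contig_csv(tmp_path):
    """Hand-built contig table: b1/b2 share a productive TRB clone, b3 is
    TRA-only, b4 has only an unproductive TRB, b5 has a Multi chain row."""
    text = (
        "barcode,is_cell,chain,v_gene,j_gene,cdr3,cdr3_nt,productive,umis,raw_clonotype_id\n"
        "b1,True,TRB,TRBV19,TRBJ2-1,CASSA,TGTGCCAGCAGTGCT,True,7,clonotype1\n"
        "b2,True,TRB,TRBV19,TRBJ2-1,CASSA,TGTGCCAGCAGTGCT,True,3,clonotype1\n"
        "b3,True,TRA,TRAV12,TRAJ33,CAVRA,TGTGCTGTGAGAGCT,True,4,clonotype2\n"
        "b4,True,TRB,TRBV19,TRBJ2-1,CASSP,TGTGCCAGCAGTGGT,False,2,clonotype3\n"
        "b5,True,Multi,,,CASSC,TGTGCCAGCAGTTGT,True,1,\n"
    )
    path = tmp_path / "contigs.csv"
    path.write_text(text)
    return path


@pytest.fixture
def bulk_tsv(tmp_path):
    """Bulk rows: two in-frame rows of the same clone merge; Out dropped."""
    text = (
        "rearrangement\tamino_acid\ttemplates\tframe_type\n"
        "TGTGCCAGCAGTGCT\tCASSA\t10\tIn\n"
        "TGTGCCAGCAGTGGA\tCASSP\t5\tOut\n"
        "TGCGCCAGCAGTGCC\tCASSA\t2\tIn\n"
    )
    path = tmp_path / "bulk.tsv"
    path.write_text(text)
    return path


def make_sample(counts, *, timepoint, patient="P1", compartment="BM",
                platform="single_cell"):
    return RepertoireSample(
        patient_id=patient, compartment=compartment,
        timepoint=Timepoint.parse(timepoint),
        counts={Clonotype(aa): k for aa, k in counts.items()},
        platform=platform)


@pytest.fixture
def small_params():
    """Fast generator settings used where full depth is not the point."""
    return SimulationParams(seed=7, n_clones=50, depth_per_sample=2000,
                            n_inc=4, n_dec=4, n_new_transient=2, n_new_stable=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
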