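import pytest

from prokannot import fixtures, refdb


def build_from_manifest(manifest, out_db, **kwargs):
    paths = manifest["paths"]
    return refdb.build_db(
        proteins_fasta=paths["proteins"],
        membership_tsv=paths["membership"],
        annotation_tables=[(s, p) for s, p in paths["annotations"]],
        out_db=out_db,
        expert_tsv=paths["expert_tsv"],
        expert_fasta=paths["expert_fasta"],
        blocklist=paths["blocklist"],
        **kwargs,
    )


@pytest.fixture(scope="session")
def ref_manifest(tmp_path_factory):
    return fixtures.gen_reference(42, tmp_path_factory.mktemp("refsrc"))


@pytest.fixture(scope="session")
def ref_db_path(ref_manifest, tmp_path_factory):
    path = tmp_path_factory.mktemp("refdb") / "db.sqlite"
    build_from_manifest(ref_manifest, path, version="1.0")
    return path


@pytest.fixture(scope="session")
def ref_db(ref_db_path):
    with refdb.RefDb(ref_db_path) as db:
        yield db


@pytest.fixture(scope="session")
def genome_truth(ref_manifest, tmp_path_factory):
    return fixtures.gen_genome(
        7, ref_manifest, tmp_path_factory.mktemp("genome"),
        n_exact=8, n_psc_mutants=3, n_pscc_mutants=3, n_sorfs=3)
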