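import pytest

import seedledger as sl


@pytest.fixture
def adb():
    """Fresh in-memory database, logged in as the bootstrap administrator,
    with the standard synthetic vocabularies registered."""
    db = sl.SeedDatabase(":memory:", login="admin")
    sl.fixtures.seed_vocabularies(db)
    yield db
    db.close()


@pytest.fixture
def pedigree():
    """Small deterministic synthetic pedigree (founders + mixed events)."""
    db = sl.fixtures.generate_fixture(n_founders=6, n_events=18, p_cross=0.5,
                                      p_mta=0.3, seed=42)
    yield db
    db.close()


@pytest.fixture
def family(adb):
    """A hand-built three-level family: two founders, a cross, a mutagenesis.

    L1 carries a transgene, L2 an endogenous mutation; X = L1 × L2;
    M = MUTAG(X) adding one more endogenous mutation.
    """
    r, lg = sl.registry, sl.lineage
    l1 = r.create_line(adb, "L1", "person-KESTREL", "Arabidopsis thaliana",
                       ecotype="Col-0")
    f1 = r.add_feature(adb, l1, sl.FeatureSpec(
        designation="Pro35S:GUS", category=sl.FeatureCategory.TRANSGENESIS,
        mutation_method="T-DNA", selectable_resistance="Kanamycin"))
    l2 = r.create_line(adb, "L2", "person-IBIS", "Arabidopsis thaliana",
                       ecotype="Ler")
    f2 = r.add_feature(adb, l2, sl.FeatureSpec(
        designation="pht1;1-1", category=sl.FeatureCategory.ENDOGENOUS,
        mutation_method="EMS"))
    x = lg.cross(adb, l1, l2, "X1")
    m = lg.mutagenize(adb, x, sl.FeatureSpec(
        designation="pht1;4-2", category=sl.FeatureCategory.ENDOGENOUS,
        mutation_method="CRISPR"), "M1")
    return dict(db=adb, l1=l1, l2=l2, x=x, m=m, f1=f1, f2=f2)
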