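import pytest

from refkit import (
    FixtureSpec,
    Lineage,
    RankSchema,
    RefRecord,
    ReferenceDatabase,
    default_primer_pair,
)


@pytest.fixture
def schema():
    return RankSchema()


def lineage(*labels, schema_len=7):
    labs = list(labels) + [""] * (schema_len - len(labels))
    return Lineage(tuple(labs))


@pytest.fixture
def staph_db(schema):
    """Three staphylococci differing only in the species epithet."""
    base = ("Bacteria", "Bacillota", "Bacilli", "Bacillales",
            "Staphylococcaceae", "Staphylococcus")
    species = ["Staphylococcus aureus", "Staphylococcus schweitzeri",
               "Staphylococcus argenteus"]
    recs = [
        RefRecord(f"st{i}", "ACGTACGTACGT", Lineage(base + (sp,)))
        for i, sp in enumerate(species)
    ]
    return ReferenceDatabase(schema, recs)


@pytest.fixture
def std_pair():
    return default_primer_pair()


@pytest.fixture(scope="session")
def fixture_spec():
    """The study-condition fixture: 50 species with every anomaly type
    except convergence (which aborts processing by design)."""
    return FixtureSpec(
        n_species=50,
        seed=20260929,
        n_duplicates=2,
        n_empty_cells=3,
        amplicon_groups=(3, 2),
    )


@pytest.fixture(scope="session")
def fixture_processed(fixture_spec):
    """Simulated 50-species database run through the full pipeline, with a
    trained classifier; shared across tests because it is deterministic."""
    from refkit import process_database, simulate_database, train

    db, truth = simulate_database(fixture_spec)
    res = process_database(db, default_primer_pair())
    model = train(res.processed)
    return model, res
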