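import pytest

from phrasemine import (
    DocumentCollection,
    Document,
    RunConfig,
    SyntheticSpec,
    TokenizerConfig,
    build_index,
    generate,
    run_pipeline,
)
from phrasemine.phrase_sets import read_outputs


@pytest.fixture
def tok_config():
    return TokenizerConfig()


@pytest.fixture
def toy_collection():
    """Six documents with a deliberately phrase-like 'zinc finger' (titles
    carry it) and a scattered counter-example."""
    rows = [
        ("1", "Zinc finger proteins. ", "The zinc finger motif binds dna. Zinc finger domains are common."),
        ("2", "Zinc finger domains in yeast.", "We survey zinc finger structure. Binding depends on the zinc finger."),
        ("3", "A study of metals.", "Trace zinc was measured. The finger of the patient was affected."),
        ("4", "Zinc finger review.", "Classic zinc finger families are reviewed here."),
        ("5", "Protein structure.", "Alpha helices and beta sheets dominate the fold."),
        ("6", "Metal binding.", "Copper and zinc bind the domain. One finger points away."),
    ]
    return DocumentCollection(
        documents=[Document.from_text(i, t, a) for i, t, a in rows]
    )


@pytest.fixture
def toy_index(toy_collection):
    return build_index(toy_collection)


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic corpus for mid-size checks (fast to index)."""
    spec = SyntheticSpec(n_docs=300, n_planted=10, n_scatter_controls=4, seed=7)
    collection, truth = generate(spec)
    return spec, collection, truth


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The full study conditions: 2,000 documents, vocabulary 500, 50
    planted phrases, title-carry 0.6 — pipeline run once, shared by the
    end-to-end checks."""
    spec = SyntheticSpec(seed=11)
    collection, truth = generate(spec)
    out_dir = tmp_path_factory.mktemp("study_out")
    config = RunConfig(seed=11)
    report = run_pipeline(collection, config, out_dir)
    outputs = read_outputs(out_dir)
    return {
        "spec": spec,
        "collection": collection,
        "truth": truth,
        "config": config,
        "report": report,
        "out_dir": out_dir,
        "outputs": outputs,
    }
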