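import pytest

from termscout.corpus_model import Corpus, RelatednessEdge, VideoRecord
from termscout.synthetic_corpus import GeneratorConfig, generate


@pytest.fixture
def tiny_corpus() -> Corpus:
    videos = [
        VideoRecord("c1", "My colonoscopy prep", "What to expect at the clinic",
                    language="en", set_label="core"),
        VideoRecord("c2", "Colonoscopy explained", "Doctor walks through the procedure",
                    language="en", set_label="core"),
        VideoRecord("n1", "Suprep review", "Honest thoughts on the prep kit",
                    language="en", set_label="neighbor:suprep", relevance="relevant"),
        VideoRecord("n2", "Best gaming chairs", "Top 10 chairs ranked",
                    language="en", set_label="neighbor:suprep", relevance="irrelevant"),
        VideoRecord("n3", "Miralax cleanse vlog", "Day before my colonoscopy",
                    language="en", set_label="neighbor:miralax", relevance="relevant"),
    ]
    edges = [
        RelatednessEdge("c1", "n1"),
        RelatednessEdge("n3", "c2"),
        RelatednessEdge("c2", "n3"),
    ]
    return Corpus(videos=videos, edges=edges, focal_term="colonoscopy")


@pytest.fixture(scope="session")
def synthetic_corpus() -> Corpus:
    cfg = GeneratorConfig(
        seed=42,
        n_core=60,
        n_expansion_per_term=30,
        planted_neighbor_terms=("suprep", "plenvu", "miralax"),
        p_edge_rel=0.2,
        p_edge_irr=0.01,
    )
    return generate(cfg)
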