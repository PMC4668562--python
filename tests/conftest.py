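import pytest

from ltrscape.annotate import annotate_genome, elements_to_dataframe
from ltrscape.families import classify_elements
from ltrscape.synthetic import PlantSpec, generate_background, plant_elements


@pytest.fixture(scope="session")
def planted():
    """A 2-Mb chromosome with a mixed set of planted elements plus truth."""
    background = generate_background(2_000_000, gc=0.4, seed=5)
    spec = PlantSpec(
        n_intact=20, n_solo=5, n_intact_no_tsd=3, n_solo_no_tsd=3, n_complex=2,
        target_K=0.02, seed=5,
    )
    genome, manifest = plant_elements(background, spec)
    return genome, manifest


@pytest.fixture(scope="session")
def annotated(planted):
    """Annotation of the shared planted genome (computed once)."""
    genome, manifest = planted
    elements = annotate_genome([genome])
    return genome, manifest, elements


@pytest.fixture(scope="session")
def classified(annotated):
    genome, manifest, elements = annotated
    families = classify_elements(elements, {genome.id: genome})
    return genome, manifest, elements, families


@pytest.fixture(scope="session")
def annotated_df(annotated):
    _, manifest, elements = annotated
    return manifest, elements_to_dataframe(elements)
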