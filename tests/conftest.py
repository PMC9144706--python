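import pytest

from olfrisk import (
    AcceptabilityCriteria,
    Catalogues,
    CompoundAnnotation,
    CompoundMeasurement,
    ExposureScenario,
    GeneratorParams,
    GroupOELRecord,
    IURRecord,
    OELRecord,
    SampleRecord,
    generate_campaign,
)
from olfrisk.types import normalize_name


def make_sample(compounds, sample_id="S1", area="Wastewater treatment",
                location="Flotation tank"):
    return SampleRecord(
        sample_id=sample_id, area=area, location=location, compounds=tuple(compounds)
    )


@pytest.fixture
def small_catalogues():
    """Hand-built catalogues exercising every tier and fallback path."""
    oels = [
        OELRecord("toluene", 384.0, "international_oel", cas="108-88-3", source_label="A"),
        OELRecord("benzene", 3.25, "international_oel", cas="71-43-2", source_label="A"),
        OELRecord("benzene", 1.6, "dnel", cas="71-43-2", source_label="B"),
        OELRecord("styrene", 300.0, "national_oel", cas="100-42-5", source_label="X"),
        OELRecord("styrene", 190.0, "national_oel", cas="100-42-5", source_label="Y"),
        OELRecord("ethanol", 1900.0, "dnel", cas="64-17-5", source_label="REACH"),
        OELRecord("naphthalene", 50.0, "national_oel", cas="91-20-3", source_label="C"),
    ]
    groups = [
        GroupOELRecord("Hydrocarbons, aliphatic, C6-C8", "aliphatic", 6, 8, 1400.0, "DE"),
        GroupOELRecord("Hydrocarbons, aliphatic, C9-C14", "aliphatic", 9, 14, 600.0, "DE"),
        GroupOELRecord("Hydrocarbon mixtures, aliphatic C5-C8", "aliphatic", 5, 8, 300.0, "LV"),
        GroupOELRecord("Hydrocarbons, aromatic, C9-C14", "aromatic", 9, 14, 100.0, "DE"),
    ]
    iur = [
        IURRecord("benzene", 7.8e-6, cas="71-43-2"),
        IURRecord("naphthalene", 3.4e-5, cas="91-20-3"),
    ]
    classes = {"71-43-2": "1A", "91-20-3": "2",
               normalize_name("benzene"): "1A", normalize_name("naphthalene"): "2"}
    annotations = {}
    for name, cas, klass, carbon in [
        ("n-heptane", "142-82-5", "aliphatic", 7),
        ("n-decane", "124-18-5", "aliphatic", 10),
        ("1,2,4-trimethylbenzene", "95-63-6", "aromatic", 9),
        ("toluene", "108-88-3", "aromatic", 7),
    ]:
        ann = CompoundAnnotation(name, klass, carbon, cas=cas)
        annotations[cas] = ann
        annotations[normalize_name(name)] = ann
    return Catalogues(oels=oels, groups=groups, iur=iur, classes=classes,
                      annotations=annotations)


@pytest.fixture(scope="session")
def default_campaign():
    """One default synthetic campaign shared across read-only tests."""
    return generate_campaign(GeneratorParams(seed=12345))


@pytest.fixture
def criteria():
    return AcceptabilityCriteria()


@pytest.fixture
def continuous_scenario():
    """Continuous lifetime exposure: CDI multiplier exactly 1."""
    return ExposureScenario(label="continuous", et=24.0, ef=365.0, ed=70.0, lt=70.0)


def cm(name, conc, cas=None, carc="none"):
    return CompoundMeasurement(name=name, concentration=conc, cas=cas,
                               carcinogen_class=carc)
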