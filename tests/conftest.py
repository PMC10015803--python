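import pytest

from vocmix import (
    ChemClass,
    ChemicalDescriptor,
    MeasurementSample,
    ReferenceRegistry,
    RegistryRecord,
    load_table3_registry,
)


def chem(name, cas="NA", chem_class=ChemClass.VOC, tvoc=True):
    return ChemicalDescriptor(name=name, cas=cas, chem_class=chem_class, tvoc_included=tvoc)


@pytest.fixture(scope="session")
def table3_registry():
    return load_table3_registry()


@pytest.fixture
def mini_registry():
    """Two-chemical registry with chronic RVs (formaldehyde 9, isopropanol 7)."""
    reg = ReferenceRegistry()
    reg.add(RegistryRecord(name="Formaldehyde", cas="59-00-0", rv=9.0))
    reg.add(RegistryRecord(name="Isopropanol", cas="67-63-0", rv=7.0))
    return reg


@pytest.fixture
def formaldehyde():
    return chem("Formaldehyde", "59-00-0", ChemClass.ALDEHYDE)


@pytest.fixture
def isopropanol():
    return chem("Isopropanol", "67-63-0")


def make_sample(concs, censored=(), salon="s1", worker="h1"):
    return MeasurementSample(
        salon_id=salon,
        worker_id=worker,
        concentrations=dict(concs),
        censored=set(censored),
    )
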