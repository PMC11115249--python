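import numpy as np
import pytest

from cyclodeps.mass import IonSpecies
from cyclodeps.residues import CyclicDepsipeptide, default_alphabet

# Hand-written monoisotopic residue masses (IUPAC sums, independent of the
# package's constants table) used to assemble worked-example peak lists.
PHE = 147.06841
LXX = 113.08406
HBA = 86.03678
LAC = 72.02113
HDA = 170.13068
HDDA = 198.16198


@pytest.fixture(scope="session")
def alphabet():
    return default_alphabet()


@pytest.fixture(scope="session")
def sodiated():
    return IonSpecies("M+Na")


@pytest.fixture(scope="session")
def protonated():
    return IonSpecies("M+H")


@pytest.fixture()
def cycle_a(alphabet):
    return CyclicDepsipeptide.from_names(
        ["Phe", "Lxx", "Hba", "Phe", "Lxx", "Hda"], alphabet
    )


@pytest.fixture()
def cycle_b(alphabet):
    return CyclicDepsipeptide.from_names(
        ["Phe", "Lxx", "Lac", "Phe", "Lxx", "Hda"], alphabet
    )


@pytest.fixture()
def cycle_c(alphabet):
    return CyclicDepsipeptide.from_names(
        ["Phe", "Lxx", "Lac", "Phe", "Lxx", "Hdda"], alphabet
    )


@pytest.fixture()
def cycle_d(alphabet):
    return CyclicDepsipeptide.from_names(
        ["Phe", "Lxx", "Hba", "Phe", "Lxx", "Hdda"], alphabet
    )


def worked_example_peaks() -> tuple[np.ndarray, np.ndarray]:
    """The published worked-example peak list for the reference sodiated
    macrocycle, assembled by hand arithmetic from the printed fragment
    m/z values (306.2035, 164.0677, the opened a-type ion 799.4562 and
    the printed 142.1345 / 86.0365 losses) extended by residue-mass sums.
    """
    b2 = 306.2035
    b3 = b2 + PHE
    b4 = b3 + 86.0365  # printed short hydroxy-acid loss
    b5 = b4 + LXX
    a0 = 799.4562
    x5 = a0 - 142.1345  # printed long-chain hydroxy-acid - CO loss
    x1 = 164.0677
    x2 = x1 + PHE
    x3 = x2 + 86.0365
    x4 = x3 + LXX
    mz = np.array([b2, b3, b4, b5, a0, x5, x1, x2, x3, x4])
    intensity = np.full(mz.size, 1e5)
    return mz, intensity


@pytest.fixture()
def fig_peaks():
    return worked_example_peaks()
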