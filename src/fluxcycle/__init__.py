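"""fluxcycle: cell-cycle-phase-resolved metabolic flux analysis.

Deconvolves pulse-chase 13C labeling measurements from synchronized (and
progressively desynchronizing) cell populations into cell-cycle-position-
specific pool sizes and mass-isotopomer distributions, then estimates
phase-specific TCA-cycle fluxes by isotopically non-stationary metabolic
flux analysis with profile-likelihood confidence intervals.
"""

from importlib import resources

from .network import (
    FluxMap,
    Metabolite,
    Network,
    NetworkFormatError,
    Reaction,
    parse_network,
    serialize_network,
    validate_steady_state,
)
from .emu import EmuNode, EmuSystem, emu_decompose
from .labeling import (
    LabelingTimeCourse,
    TracerSpec,
    correct_natural_abundance,
    simulate_labeling,
    steady_state_mids,
)
from .bruteforce import simulate_labeling_bruteforce

__version__ = "0.1.0"


def default_network_text() -> str:
    """The bundled TCA network definition document."""
    return resources.files("fluxcycle.data").joinpath("tca.network").read_text()


def load_default_network() -> Network:
    return parse_network(default_network_text())


def default_redox_accounting() -> dict:
    import yaml

    text = resources.files("fluxcycle.data").joinpath("redox.yaml").read_text()
    return yaml.safe_load(text)
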