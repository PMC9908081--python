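"""Exception hierarchy for ribbonquant.

Every operational failure raises a subclass of :class:`RibbonQuantError`
so callers can catch pipeline errors without masking programming errors.
"""


class RibbonQuantError(Exception):
    """Base class for all ribbonquant errors."""


# --- timing ---------------------------------------------------------------
class InvalidConstants(RibbonQuantError):
    """A timing constant is negative or otherwise out of range."""


class InsufficientShots(RibbonQuantError):
    """Fewer test shots than required to estimate mean and SD."""


class NoValveEvent(RibbonQuantError):
    """No valve-opening dip/drop signature found in the pneumatic trace."""


class MissingChannel(RibbonQuantError):
    """A required sensor channel is empty or absent."""


class NegativeMechanicsDelay(RibbonQuantError):
    """Valve opened before the nominal LN2 pressurization time."""


# --- irradiance -----------------------------------------------------------
class InvalidVoltage(RibbonQuantError):
    """Photodiode voltage outside the calibrated (non-negative) range."""


class NoSignal(RibbonQuantError):
    """Image carries no gray value above background."""


# --- ephys ----------------------------------------------------------------
class InsufficientBaseline(RibbonQuantError):
    """Too few samples in the pre-stimulus window."""


class NoEvent(RibbonQuantError):
    """No threshold crossing after light onset."""


class InvalidKinetics(RibbonQuantError):
    """Event kinetics are unphysical (decay faster than rise)."""


# --- tomogram quantification ---------------------------------------------
class MissingStructure(RibbonQuantError):
    """A required annotation structure (membrane, PD, ribbon) is absent."""


class SplitUndefined(RibbonQuantError):
    """Ribbon has no extent along the membrane axis; halves undefined."""


class PlacementError(RibbonQuantError):
    """Synthetic vesicle placement failed after the retry cap."""


# --- statistics -----------------------------------------------------------
class DegenerateData(RibbonQuantError):
    """Groups have zero variance; the comparison is undefined."""
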