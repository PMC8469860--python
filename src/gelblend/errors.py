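"""Exception types raised across the package."""


class GelblendError(Exception):
    """Base class for package errors."""


class ConfigurationError(GelblendError):
    """Invalid monomer template, residue name or run configuration."""


class PackingError(GelblendError):
    """Amorphous-cell growth failed at the requested density."""

    def __init__(self, message, achieved_density=None):
        super().__init__(message)
        self.achieved_density = achieved_density


class GeometryError(GelblendError):
    """Simulation-cell geometry incompatible with the requested cutoff."""


class DivergenceError(GelblendError):
    """Non-finite energy encountered during minimization."""


class MinimizationError(GelblendError):
    """Minimizer failed to reach the requested force tolerance."""


class InstabilityError(GelblendError):
    """Dynamics became unstable (temperature explosion)."""

    def __init__(self, message, step=None, stage=None):
        super().__init__(message)
        self.step = step
        self.stage = stage


class DataError(GelblendError):
    """Missing or inconsistent experimental data fields."""


class LabelingError(GelblendError):
    """Atoms lack the species labels required by the analysis."""
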