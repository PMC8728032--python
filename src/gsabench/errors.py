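"""Exception types shared across the package.

CLI exit-code mapping: ParameterError -> 2 (usage), DataError -> 3 (data).
"""

import numpy as np


class ParameterError(ValueError):
    """An argument is outside its admissible range."""


class DataError(ValueError):
    """Input data violate a structural requirement (parse errors, shape
    mismatches, degenerate columns, missing ids)."""


class SingularMatrixError(np.linalg.LinAlgError):
    """A covariance matrix required by a test is numerically singular."""
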