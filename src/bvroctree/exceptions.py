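"""Exception hierarchy.

All library errors derive from :class:`BvrocError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class BvrocError(Exception):
    """Base class for all bvroctree errors."""


class InputError(BvrocError, ValueError):
    """Malformed input: wrong shapes, non-finite values, bad labels, bad files."""


class DegenerateLabelsError(BvrocError, ValueError):
    """Only one class present where both are required (e.g. for an AUC)."""


class DegenerateSplitError(BvrocError, ValueError):
    """No usable split threshold exists (all derived values identical)."""


class FeatureExhaustionError(BvrocError, RuntimeError):
    """Every feature is excluded; no node can be formed."""


class TreeSchemaError(BvrocError, ValueError):
    """A serialized tree does not match the expected JSON schema/version."""
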