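"""Exception hierarchy shared across the package."""


class IdpbindError(Exception):
    """Base class for all package errors."""


class InputError(IdpbindError, ValueError):
    """Malformed or inconsistent input data."""


class AlphabetError(InputError):
    """A sequence contains a character outside its alphabet."""

    def __init__(self, char: str, position: int, alphabet: str):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position} "
            f"(1-based); allowed alphabet: {alphabet}"
        )


class ParameterError(IdpbindError, ValueError):
    """A parameter lies outside its allowed domain."""


class UndefinedStoichiometryError(IdpbindError, ValueError):
    """Charge-matching ratio requested for charges of the wrong sign or zero."""


class ModelDomainError(IdpbindError, ValueError):
    """A model was evaluated outside the domain where it is defined."""


class ConfigError(IdpbindError, ValueError):
    """Workflow configuration failed validation; carries the error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(str(e) for e in self.errors))
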