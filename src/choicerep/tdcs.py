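"""Small helpers for the direct-current stimulation protocol."""

__all__ = ["current_density"]


def current_density(current_ma: float = 1.0, width_cm: float = 5.0, height_cm: float = 5.0) -> float:
    """Current density of a rectangular scalp electrode in mA/cm^2.

    The study protocol drives 1 mA through 5 x 5 cm sponge electrodes,
    i.e. 0.04 mA/cm^2.
    """
    if current_ma <= 0 or width_cm <= 0 or height_cm <= 0:
        raise ValueError("current and electrode dimensions must be positive")
    return current_ma / (width_cm * height_cm)
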