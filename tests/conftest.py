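import numpy as np
import pytest

from retinotilt import StimulusSpec


def cafe_wall_oracle(spec: StimulusSpec) -> np.ndarray:
    """Independent brute-force Café Wall construction (pure loops).

    Recomputes every pixel from first principles: row bands, per-row
    wraparound shift, tile parity, interior mortar strips.
    """
    height = spec.rows * spec.tile_px + (spec.rows - 1) * spec.mortar_px
    width = spec.cols * spec.tile_px
    img = np.empty((height, width))
    period = spec.tile_px + spec.mortar_px
    for y in range(height):
        r = min(y // period, spec.rows - 1)
        within = y - r * period
        if within >= spec.tile_px:  # mortar strip below tile row r
            img[y, :] = spec.lum_mortar
            continue
        shift = int(np.floor(r * spec.shift_frac * spec.tile_px + 0.5))
        for x in range(width):
            tile = ((x - shift) % width) // spec.tile_px
            parity = (tile + (0 if spec.start_dark else 1)) % 2
            img[y, x] = spec.lum_dark if parity == 0 else spec.lum_light
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(20170908)
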