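"""Colorimetry constants pinned by the brightness pipeline.

CIE 1931 2-degree standard observer color-matching functions and the D65
illuminant spectral power distribution, both on the 380-730 nm grid at
10 nm steps (36 points), plus the sRGB (D65) conversion matrix and gamma.
"""

import numpy as np

# columns: xbar, ybar, zbar at 380, 390, ..., 730 nm
CIE_1931_2DEG = np.array([
    [0.001368, 0.000039, 0.006450],
    [0.004243, 0.000120, 0.020050],
    [0.014310, 0.000396, 0.067850],
    [0.043510, 0.001210, 0.207400],
    [0.134380, 0.004000, 0.645600],
    [0.283900, 0.011600, 1.385600],
    [0.348280, 0.023000, 1.747060],
    [0.336200, 0.038000, 1.772110],
    [0.290800, 0.060000, 1.669200],
    [0.195360, 0.090980, 1.287640],
    [0.095640, 0.139020, 0.812950],
    [0.032010, 0.208020, 0.465180],
    [0.004900, 0.323000, 0.272000],
    [0.009300, 0.503000, 0.158200],
    [0.063270, 0.710000, 0.078250],
    [0.165500, 0.862000, 0.042160],
    [0.290400, 0.954000, 0.020300],
    [0.433450, 0.994950, 0.008750],
    [0.594500, 0.995000, 0.003900],
    [0.762100, 0.952000, 0.002100],
    [0.916300, 0.870000, 0.001650],
    [1.026300, 0.757000, 0.001100],
    [1.062200, 0.631000, 0.000800],
    [1.002600, 0.503000, 0.000340],
    [0.854450, 0.381000, 0.000190],
    [0.642400, 0.265000, 0.000050],
    [0.447900, 0.175000, 0.000020],
    [0.283500, 0.107000, 0.000000],
    [0.164900, 0.061000, 0.000000],
    [0.087400, 0.032000, 0.000000],
    [0.046770, 0.017000, 0.000000],
    [0.022700, 0.008210, 0.000000],
    [0.011359, 0.004102, 0.000000],
    [0.005790, 0.002091, 0.000000],
    [0.002899, 0.001047, 0.000000],
    [0.001440, 0.000520, 0.000000],
])

# relative spectral power of D65, same grid (100 at 560 nm)
D65 = np.array([
    49.9755, 54.6482, 82.7549, 91.4860, 93.4318, 86.6823, 104.8650, 117.0080,
    117.8120, 114.8610, 115.9230, 108.8110, 109.3540, 107.8020, 104.7900,
    107.6890, 104.4050, 104.0460, 100.0000, 96.3342, 95.7880, 88.6856,
    90.0062, 89.5991, 87.6987, 83.2886, 83.6992, 80.0268, 80.2146, 82.2778,
    78.2842, 69.7213, 71.6091, 74.3490, 61.6040, 69.8856,
])

# linear XYZ (D65 white) -> linear sRGB
XYZ_TO_SRGB = np.array([
    [3.2406255, -1.5372080, -0.4986286],
    [-0.9689307, 1.8757561, 0.0415175],
    [0.0557101, -0.2040211, 1.0569959],
])


def srgb_companding(linear):
    """Standard sRGB gamma: 12.92c below 0.0031308, else 1.055c^(1/2.4)-0.055."""
    c = np.asarray(linear, dtype=float)
    out = np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.power(np.maximum(c, 0.0), 1 / 2.4) - 0.055)
    return out
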