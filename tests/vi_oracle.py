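"""Independent naive re-implementations of every published index formula.

Deliberately scalar, loop-based and separate from the package code paths:
these serve as arithmetic oracles in tests.  `R` is a plain function
wavelength -> scalar reflectance for one sample.
"""

import math


def _mean(vals):
    return sum(vals) / len(vals)


def oracle_vi(name, R, wavelengths):
    """One sample's index value from scalar arithmetic; NaN when undefined."""

    def region_mean(lo, hi):
        vals = [R(w) for w in wavelengths if lo <= w <= hi]
        return _mean(vals)

    def div(a, b):
        return float("nan") if b == 0 else a / b

    def root(x):
        return float("nan") if x < 0 else math.sqrt(x)

    if name == "NDVI":
        return div(R(810) - R(680), R(810) + R(680))
    if name == "RVI":
        return div(R(810), R(680))
    if name == "DVI":
        return R(810) - R(680)
    if name == "OSAVI":
        return (1 + 0.16) * div(R(800) - R(670), R(800) + R(670) + 0.16)
    if name == "PRI":
        return div(R(570) - R(531), R(570) + R(531))
    if name == "WDRVI":
        return div(0.2 * R(800) - R(670), 0.2 * R(800) + R(670)) + (1 - 0.2) / (1 + 0.2)
    if name == "VOG":
        return div(R(740), R(720))
    if name == "CIred-edge":
        return div(R(790), R(720)) - 1
    if name == "mND705":
        return div(R(750) - R(705), R(750) + R(705) - 2 * R(445))
    if name == "mSR705":
        return div(R(750) - R(445), R(705) - R(445))
    if name == "EVI-1":
        return 2.5 * div(R(860) - R(645), 1 + R(860) + 6 * R(645) - 7.5 * R(470))
    if name == "MCARI2":
        num = 1.5 * (2.5 * (R(800) - R(670)) - 1.3 * (R(800) - R(550)))
        den = root((2 * R(800) + 1) ** 2 - 6 * R(800) + 5 * root(R(670))) - 0.5
        return div(num, den)
    if name == "MTVI2":
        num = 1.5 * (1.2 * (R(800) - R(550)) - 2.5 * (R(670) - R(550)))
        den = root((2 * R(800) + 1) ** 2 - (6 * R(800) - 5 * root(R(670))) - 0.5)
        return div(num, den)
    if name == "SIPI":
        return div(R(800) - R(445), R(800) - R(680))
    if name == "MTCI":
        return div(R(790) - R(720), R(720) - R(670))
    if name == "DDn":
        return 2 * R(710) - R(660) - R(760)
    if name == "TCARI/OSAVI":
        tcari = 3 * ((R(700) - R(670)) - 0.2 * (R(700) - R(550)) * div(R(700), R(670)))
        osavi = (1 + 0.16) * div(R(800) - R(670), R(800) + R(670) + 0.16)
        return div(tcari, osavi)
    if name == "MSAVI2":
        nir = region_mean(760, 900)
        red = region_mean(630, 690)
        return 0.5 * (2 * nir + 1 - root((2 * nir + 1) ** 2 - 8 * (nir - red)))
    if name == "REP":
        return 700 + 40 * div((R(670) + R(780)) / 2 - R(700), R(740) - R(700))
    if name == "DD":
        return (R(749) - R(720)) - (R(701) - R(672))
    if name == "VOG-2":
        return div(R(734) - R(747), R(715) + R(726))
    raise KeyError(name)


def oracle_two_band(index_type, r1, r2):
    if index_type == "ND":
        return float("nan") if r1 + r2 == 0 else (r1 - r2) / (r1 + r2)
    if index_type == "SR":
        return float("nan") if r2 == 0 else r1 / r2
    if index_type == "DVI":
        return r1 - r2
    raise KeyError(index_type)


def oracle_r2(observed, predicted):
    m = _mean(observed)
    sse = sum((o - p) ** 2 for o, p in zip(observed, predicted))
    sst = sum((o - m) ** 2 for o in observed)
    return 1 - sse / sst


def oracle_rmse(observed, predicted):
    return math.sqrt(_mean([(p - o) ** 2 for o, p in zip(observed, predicted)]))
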