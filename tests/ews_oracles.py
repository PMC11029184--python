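"""Hand-coded nested-conditional scorers for the four EWS systems.

Written directly from the published charts as plain if/elif chains,
independently of the band-table implementation, to serve as the oracle
in equivalence tests.
"""


def news_oracle(hr, sbp, rr, temp, spo2, on_o2, avpu) -> int:
    s = 0
    if rr <= 8:
        s += 3
    elif rr <= 11:
        s += 1
    elif rr <= 20:
        s += 0
    elif rr <= 24:
        s += 2
    else:
        s += 3
    if spo2 <= 91:
        s += 3
    elif spo2 <= 93:
        s += 2
    elif spo2 <= 95:
        s += 1
    if on_o2:
        s += 2
    if temp <= 35.0:
        s += 3
    elif temp <= 36.0:
        s += 1
    elif temp <= 38.0:
        s += 0
    elif temp <= 39.0:
        s += 1
    else:
        s += 2
    if sbp <= 90:
        s += 3
    elif sbp <= 100:
        s += 2
    elif sbp <= 110:
        s += 1
    elif sbp <= 219:
        s += 0
    else:
        s += 3
    if hr <= 40:
        s += 3
    elif hr <= 50:
        s += 1
    elif hr <= 90:
        s += 0
    elif hr <= 110:
        s += 1
    elif hr <= 130:
        s += 2
    else:
        s += 3
    if avpu != "A":
        s += 3
    return s


def mews_oracle(hr, sbp, rr, temp, avpu) -> int:
    s = 0
    if sbp <= 70:
        s += 3
    elif sbp <= 80:
        s += 2
    elif sbp <= 100:
        s += 1
    elif sbp <= 199:
        s += 0
    else:
        s += 2
    if hr <= 40:
        s += 2
    elif hr <= 50:
        s += 1
    elif hr <= 100:
        s += 0
    elif hr <= 110:
        s += 1
    elif hr <= 129:
        s += 2
    else:
        s += 3
    if rr <= 8:
        s += 2
    elif rr <= 14:
        s += 0
    elif rr <= 20:
        s += 1
    elif rr <= 29:
        s += 2
    else:
        s += 3
    if temp < 35.0:
        s += 2
    elif temp <= 38.4:
        s += 0
    else:
        s += 2
    s += {"A": 0, "V": 1, "P": 2, "U": 3}[avpu]
    return s


def sews_oracle(hr, sbp, rr, temp, spo2, avpu) -> int:
    s = 0
    if rr <= 8:
        s += 2
    elif rr <= 20:
        s += 0
    elif rr <= 30:
        s += 1
    elif rr <= 35:
        s += 2
    else:
        s += 3
    if spo2 <= 84:
        s += 3
    elif spo2 <= 89:
        s += 2
    elif spo2 <= 92:
        s += 1
    if temp < 34.0:
        s += 3
    elif temp < 35.0:
        s += 2
    elif temp < 36.0:
        s += 1
    elif temp < 38.0:
        s += 0
    elif temp < 39.0:
        s += 1
    else:
        s += 2
    if sbp <= 69:
        s += 3
    elif sbp <= 79:
        s += 2
    elif sbp <= 99:
        s += 1
    elif sbp <= 199:
        s += 0
    else:
        s += 3
    if hr <= 29:
        s += 3
    elif hr <= 39:
        s += 2
    elif hr <= 49:
        s += 1
    elif hr <= 99:
        s += 0
    elif hr <= 109:
        s += 1
    elif hr <= 129:
        s += 2
    else:
        s += 3
    s += {"A": 0, "V": 1, "P": 2, "U": 3}[avpu]
    return s


def cews_oracle(hr, sbp, rr, temp, spo2, avpu) -> int:
    s = 0
    if hr <= 44:
        s += 3
    elif hr <= 50:
        s += 2
    elif hr <= 54:
        s += 1
    elif hr <= 100:
        s += 0
    elif hr <= 109:
        s += 1
    elif hr <= 126:
        s += 2
    else:
        s += 3
    if sbp <= 84:
        s += 3
    elif sbp <= 95:
        s += 2
    elif sbp <= 100:
        s += 1
    elif sbp <= 151:
        s += 0
    elif sbp <= 159:
        s += 1
    elif sbp <= 178:
        s += 2
    else:
        s += 3
    if rr <= 6:
        s += 3
    elif rr <= 10:
        s += 2
    elif rr <= 13:
        s += 1
    elif rr <= 25:
        s += 0
    elif rr <= 28:
        s += 1
    elif rr <= 33:
        s += 2
    else:
        s += 3
    if temp < 35.5:
        s += 3
    elif temp < 36.0:
        s += 2
    elif temp < 36.3:
        s += 1
    elif temp < 37.4:
        s += 0
    elif temp < 37.7:
        s += 1
    elif temp < 38.2:
        s += 2
    else:
        s += 3
    if spo2 <= 84:
        s += 3
    elif spo2 <= 90:
        s += 2
    elif spo2 <= 93:
        s += 1
    s += {"A": 0, "V": 1, "P": 2, "U": 3}[avpu]
    return s
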