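"""Minimal EDF (European Data Format) reader/writer.

Supports exactly what the pipeline needs: multichannel int16 signals with a
shared sampling rate, physical scaling per channel, and an integer trigger
channel.  Record duration is fixed at one second; the true sample count is
stowed in the recording-id field so trailing zero padding can be trimmed on
read.
"""

from __future__ import annotations

import numpy as np

_HDR = 256  # bytes, fixed header
_SIG = 256  # bytes, per-signal header

TRIGGER_LABEL = "TRIG"


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    labels: list[str],
    data: np.ndarray,
    rate: float,
    physical_dim: str = "uV",
) -> None:
    """Write ``data`` (n_channels x n_samples) to ``path`` as EDF.

    ``rate`` must be a positive integer number of samples per second; the
    signal is zero-padded to a whole number of one-second records.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise ValueError("data must be (n_channels, n_samples) matching labels")
    if rate <= 0 or rate != int(rate):
        raise ValueError(f"rate must be a positive integer, got {rate}")
    spr = int(rate)
    nchan, nsamp = data.shape
    nrec = int(np.ceil(nsamp / spr))
    padded = np.zeros((nchan, nrec * spr))
    padded[:, :nsamp] = data

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = digital.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X", 80))
        fh.write(_ascii(f"NSAMP={nsamp}", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(_HDR + _SIG * nchan, 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(nrec, 8))
        fh.write(_ascii("1", 8))
        fh.write(_ascii(nchan, 4))
        for lab in labels:
            fh.write(_ascii(lab, 16))
        for _ in labels:
            fh.write(_ascii("", 80))
        for lab in labels:
            fh.write(_ascii("" if lab == TRIGGER_LABEL else physical_dim, 8))
        for v in phys_min:
            fh.write(_ascii(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_ascii(f"{v:.8g}"[:8], 8))
        for _ in labels:
            fh.write(_ascii(dig_min, 8))
        for _ in labels:
            fh.write(_ascii(dig_max, 8))
        for _ in labels:
            fh.write(_ascii("", 80))
        for _ in labels:
            fh.write(_ascii(spr, 8))
        for _ in labels:
            fh.write(_ascii("", 32))
        # data records: per record, per signal, spr int16 samples
        for r in range(nrec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> tuple[list[str], np.ndarray, float]:
    """Read an EDF file, returning (labels, data, rate)."""
    with open(path, "rb") as fh:
        hdr = fh.read(_HDR)
        if len(hdr) < _HDR:
            raise ValueError(f"{path}: truncated EDF header")
        recording_id = hdr[88:168].decode("ascii").strip()
        nrec = int(hdr[236:244])
        rec_dur = float(hdr[244:252])
        nchan = int(hdr[252:256])
        sig = fh.read(_SIG * nchan)

        def field(offset, width, cast=str):
            out = []
            for i in range(nchan):
                raw = sig[offset * nchan + i * width : offset * nchan + (i + 1) * width]
                out.append(cast(raw.decode("ascii").strip()))
            return out

        labels = field(0, 16)
        # cumulative byte offsets: label 16, transducer 80, phys_dim 8,
        # phys_min/max 8 each, dig_min/max 8 each, prefilter 80, spr 8
        phys_min = np.array(field(104, 8, float))
        phys_max = np.array(field(112, 8, float))
        dig_min = np.array(field(120, 8, float))
        dig_max = np.array(field(128, 8, float))
        spr = field(216, 8, int)
        if len(set(spr)) != 1:
            raise ValueError("mixed samples-per-record not supported")
        spr = spr[0]
        rate = spr / rec_dur

        raw = np.frombuffer(fh.read(2 * nchan * spr * nrec), dtype="<i2")
    raw = raw.reshape(nrec, nchan, spr).transpose(1, 0, 2).reshape(nchan, -1)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (raw - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    if recording_id.startswith("NSAMP="):
        nsamp = int(recording_id.split("=", 1)[1])
        data = data[:, :nsamp]
    return labels, data, rate


def extract_triggers(labels: list[str], data: np.ndarray, rate: float):
    """Return (time, code) pairs from the TRIG channel (nonzero samples)."""
    if TRIGGER_LABEL not in labels:
        return []
    trig = np.round(data[labels.index(TRIGGER_LABEL)]).astype(int)
    idx = np.nonzero(trig)[0]
    return [(i / rate, int(trig[i])) for i in idx]
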