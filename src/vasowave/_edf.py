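"""Minimal EDF (European Data Format) codec.

Implements the fixed-layout EDF header (256 bytes + 256 bytes per signal)
and 16-bit little-endian sample records — enough to round-trip
single/multi-channel physiological recordings. Data records are one second
long, so every channel must have an integer sampling rate.

Invalid/missing samples are stored as the sentinel digital value -32768,
which lies outside the declared digital range [-32767, 32767]; the reader
masks them out. The true per-channel sample count is stashed in the
signal's reserved field (``nsamples=<int>``) so zero-padding of the final
record can be trimmed on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vasowave.errors import FormatError, SchemaError

_SENTINEL = -32768
_DIG_MIN = -32767
_DIG_MAX = 32767


@dataclass
class EdfChannel:
    """One signal to be written to / read from an EDF file."""

    label: str
    sample_rate: int
    samples: np.ndarray
    mask: np.ndarray | None = None  # True = invalid sample
    physical_dimension: str = ""
    transducer: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.samples.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.samples.shape:
            raise FormatError("mask and samples must have equal length")


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width, b" ")


def _num(value, width: int) -> bytes:
    text = _num_str(value, width)
    return _fixed(text, width)


def _num_str(value, width: int) -> str:
    """Shortest %g rendering of ``value`` that fits ``width`` ASCII chars."""
    for prec in range(10, 0, -1):
        text = f"{value:.{prec}g}"
        if len(text) <= width:
            return text
    raise FormatError(f"cannot represent {value!r} in {width} chars")


def _physical_range(samples: np.ndarray, mask: np.ndarray | None = None
                    ) -> tuple[float, float]:
    """Header-representable physical range guaranteed to cover the data.

    Returns the values as they will be parsed back from the 8-char header
    fields, nudged outward until they bracket the data.
    """
    samples = np.asarray(samples, dtype=float)
    if mask is not None:
        samples = samples[~np.asarray(mask, dtype=bool)]
    if samples.size == 0:
        return 0.0, 1.0
    vmin, vmax = float(np.min(samples)), float(np.max(samples))
    if vmax <= vmin:
        vmax = vmin + 1.0
    span = vmax - vmin
    pmin, pmax = vmin, vmax
    for _ in range(20):
        pmin = float(_num_str(pmin, 8))
        if pmin <= vmin:
            break
        pmin -= 1e-3 * span
    for _ in range(20):
        pmax = float(_num_str(pmax, 8))
        if pmax >= vmax:
            break
        pmax += 1e-3 * span
    return pmin, pmax


def write_edf(path, channels: list[EdfChannel], *, patient_id: str = "X",
              recording_id: str = "vasowave") -> None:
    """Write channels to ``path`` as EDF with 1-second data records."""
    if not channels:
        raise FormatError("at least one channel required")
    for ch in channels:
        if ch.sample_rate <= 0 or ch.sample_rate != int(ch.sample_rate):
            raise FormatError(
                f"EDF dialect requires a positive integer sampling rate, got {ch.sample_rate}"
            )
        if ch.samples.size == 0:
            raise FormatError("cannot write an empty channel")

    n_records = max(int(np.ceil(ch.samples.size / int(ch.sample_rate))) for ch in channels)
    ns = len(channels)
    header_bytes = 256 * (ns + 1)

    digital: list[np.ndarray] = []
    phys_ranges: list[tuple[float, float]] = []
    for ch in channels:
        sr = int(ch.sample_rate)
        pmin, pmax = _physical_range(ch.samples, ch.mask)
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.full(n_records * sr, _SENTINEL, dtype=np.int16)
        n = ch.samples.size
        quant = np.rint((ch.samples - pmin) * scale).astype(np.int64) + _DIG_MIN
        quant = np.clip(quant, _DIG_MIN, _DIG_MAX)
        dig[:n] = quant.astype(np.int16)
        dig[:n][ch.mask] = _SENTINEL
        digital.append(dig)
        phys_ranges.append((pmin, pmax))

    with open(path, "wb") as fh:
        fh.write(_fixed("0", 8))
        fh.write(_fixed(patient_id, 80))
        fh.write(_fixed(recording_id, 80))
        fh.write(_fixed("01.01.00", 8))
        fh.write(_fixed("00.00.00", 8))
        fh.write(_num(header_bytes, 8))
        fh.write(_fixed("", 44))
        fh.write(_num(n_records, 8))
        fh.write(_num(1, 8))
        fh.write(_num(ns, 4))

        fh.write(b"".join(_fixed(ch.label, 16) for ch in channels))
        fh.write(b"".join(_fixed(ch.transducer, 80) for ch in channels))
        fh.write(b"".join(_fixed(ch.physical_dimension, 8) for ch in channels))
        fh.write(b"".join(_num(pr[0], 8) for pr in phys_ranges))
        fh.write(b"".join(_num(pr[1], 8) for pr in phys_ranges))
        fh.write(b"".join(_num(_DIG_MIN, 8) for _ in channels))
        fh.write(b"".join(_num(_DIG_MAX, 8) for _ in channels))
        fh.write(b"".join(_fixed("", 80) for _ in channels))
        fh.write(b"".join(_num(int(ch.sample_rate), 8) for ch in channels))
        fh.write(b"".join(_fixed(f"nsamples={ch.samples.size}", 32) for ch in channels))

        for rec in range(n_records):
            for ch_i, ch in enumerate(channels):
                sr = int(ch.sample_rate)
                block = digital[ch_i][rec * sr:(rec + 1) * sr]
                fh.write(block.astype("<i2").tobytes())


def read_edf(path) -> dict[str, EdfChannel]:
    """Read all channels of an EDF file keyed by (stripped) label."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise SchemaError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise SchemaError(f"{path}: malformed EDF header") from exc
        if ns <= 0:
            raise SchemaError(f"{path}: no signals in EDF header")

        def fields(width: int) -> list[str]:
            blob = fh.read(width * ns)
            return [blob[i * width:(i + 1) * width].decode("ascii").strip()
                    for i in range(ns)]

        labels = fields(16)
        transducers = fields(80)
        phys_dims = fields(8)
        phys_min = [float(v) for v in fields(8)]
        phys_max = [float(v) for v in fields(8)]
        dig_min = [int(float(v)) for v in fields(8)]
        dig_max = [int(float(v)) for v in fields(8)]
        fields(80)  # prefiltering
        spr = [int(v) for v in fields(8)]
        reserved = fields(32)

        per_record = sum(spr)
        raw = np.frombuffer(fh.read(n_records * per_record * 2), dtype="<i2")

    if raw.size < n_records * per_record:
        raise SchemaError(f"{path}: truncated EDF data section")
    raw = raw.reshape(n_records, per_record)

    channels: dict[str, EdfChannel] = {}
    offset = 0
    for i in range(ns):
        dig = raw[:, offset:offset + spr[i]].reshape(-1).astype(np.int64)
        offset += spr[i]
        n_samples = dig.size
        for token in reserved[i].split():
            if token.startswith("nsamples="):
                n_samples = min(int(token[9:]), dig.size)
        dig = dig[:n_samples]
        mask = dig == _SENTINEL
        span = dig_max[i] - dig_min[i]
        scale = (phys_max[i] - phys_min[i]) / span if span else 1.0
        phys = (dig - dig_min[i]) * scale + phys_min[i]
        phys[mask] = np.nan
        sr = spr[i] / record_dur
        channels[labels[i]] = EdfChannel(
            label=labels[i],
            sample_rate=int(round(sr)),
            samples=phys,
            mask=mask,
            physical_dimension=phys_dims[i],
            transducer=transducers[i],
        )
    return channels


def quantization_step(samples: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Physical value of one digital unit for the range a write would use."""
    pmin, pmax = _physical_range(samples, mask)
    return (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
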