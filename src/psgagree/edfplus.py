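"""Minimal EDF+ annotation-only files (the TAL track).

Scoring annotations travel as EDF+ "Time-stamped Annotations Lists":
each data record holds NUL-terminated TALs of the form
``+onset[\\x15duration]\\x14text\\x14``, stored in a single
``EDF Annotations`` signal.  Only the annotation track is implemented —
no waveform signals are read or written; the analysis consumes
scorings, not signals.

Numbers are serialized with Python's shortest round-tripping ``str`` so
that write -> read is an exact identity on onsets and durations.
"""

from __future__ import annotations

import math
import os

from .errors import ParseError

_DUR_SEP = b"\x15"
_TEXT_SEP = b"\x14"
_TAL_END = b"\x00"

# Annotations per data record; keeps records comfortably under the
# conventional 61440-byte EDF record ceiling.
_ANNS_PER_RECORD = 64


def _fmt_number(x: float) -> str:
    """Shortest exact decimal; EDF+ onsets must carry an explicit sign."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def _header_field(text: str, width: int) -> bytes:
    data = text.encode("ascii")
    if len(data) > width:
        raise ValueError(f"header field too long: {text!r}")
    return data.ljust(width)


def _tal(onset: float, duration: float, text: str) -> bytes:
    onset_s = ("+" if onset >= 0 else "") + _fmt_number(onset)
    out = onset_s.encode("ascii")
    if duration > 0:
        out += _DUR_SEP + _fmt_number(duration).encode("ascii")
    out += _TEXT_SEP + text.encode("utf-8") + _TEXT_SEP + _TAL_END
    return out


def write_edfplus(rec, path: os.PathLike | str) -> None:
    """Write a ScoredRecording as an EDF+ annotation-only file."""
    from .vocab import LIGHTS_OFF, LIGHTS_ON
    from .annotations import Annotation

    anns: list[Annotation] = [Annotation(rec.lights_off, 0.0, LIGHTS_OFF)]
    anns.extend(rec.annotations)
    anns.append(Annotation(rec.lights_on, 0.0, LIGHTS_ON))

    chunks = [anns[i:i + _ANNS_PER_RECORD]
              for i in range(0, len(anns), _ANNS_PER_RECORD)]
    records = []
    for chunk in chunks:
        # Every record starts with its time-keeping TAL (empty text).
        body = _tal(chunk[0].onset, 0.0, "")
        for a in chunk:
            body += _tal(a.onset, a.duration, a.label)
        records.append(body)

    samples_per_record = max(math.ceil(len(r) / 2) for r in records)
    n_records = len(records)

    header = b"".join([
        _header_field("0", 8),                      # version
        _header_field("X X X X", 80),               # local patient id
        _header_field("Startdate X X X X", 80),     # local recording id
        _header_field("01.01.00", 8),               # startdate
        _header_field("00.00.00", 8),               # starttime
        _header_field(str(256 + 256), 8),           # header bytes
        _header_field("EDF+C", 44),                 # reserved
        _header_field(str(n_records), 8),
        _header_field("0", 8),                      # record duration (s)
        _header_field("1", 4),                      # number of signals
        # signal header (one signal)
        _header_field("EDF Annotations", 16),
        _header_field("", 80),                      # transducer
        _header_field("", 8),                       # physical dimension
        _header_field("-1", 8),                     # physical min
        _header_field("1", 8),                      # physical max
        _header_field("-32768", 8),                 # digital min
        _header_field("32767", 8),                  # digital max
        _header_field("", 80),                      # prefiltering
        _header_field(str(samples_per_record), 8),
        _header_field("", 32),                      # reserved
    ])
    assert len(header) == 512

    with open(path, "wb") as fh:
        fh.write(header)
        for body in records:
            fh.write(body.ljust(2 * samples_per_record, _TAL_END))


def _parse_tal_number(data: bytes, where: str) -> float:
    try:
        return float(data.decode("ascii"))
    except (UnicodeDecodeError, ValueError) as exc:
        raise ParseError(f"{where}: malformed TAL timestamp {data!r}") from exc


def read_edfplus_raw(path: os.PathLike | str) -> list[tuple[str, float, float]]:
    """Parse the TAL track of an EDF+ file into (label, onset, duration)
    triples.  Time-keeping TALs (empty text) are skipped."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ParseError(f"{path}: truncated EDF header")
        try:
            n_records = int(header[236:244].decode("ascii").strip())
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ParseError(f"{path}: malformed EDF header") from exc
        sig_header = fh.read(256 * ns)
        if len(sig_header) < 256 * ns:
            raise ParseError(f"{path}: truncated signal header")
        labels = [sig_header[i * 16:(i + 1) * 16].decode("ascii").strip()
                  for i in range(ns)]
        nsamp_off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        nsamps = [int(sig_header[nsamp_off + i * 8: nsamp_off + (i + 1) * 8]
                      .decode("ascii").strip()) for i in range(ns)]
        try:
            ann_idx = labels.index("EDF Annotations")
        except ValueError:
            raise ParseError(f"{path}: no 'EDF Annotations' signal") from None

        out: list[tuple[str, float, float]] = []
        for rec_no in range(n_records):
            for i in range(ns):
                data = fh.read(2 * nsamps[i])
                if i != ann_idx:
                    continue
                for tal in data.split(_TAL_END):
                    if not tal:
                        continue
                    fields = tal.split(_TEXT_SEP)
                    if len(fields) < 2:
                        raise ParseError(
                            f"{path}: record {rec_no}: malformed TAL {tal!r}")
                    stamp = fields[0]
                    if _DUR_SEP in stamp:
                        onset_b, dur_b = stamp.split(_DUR_SEP, 1)
                        duration = _parse_tal_number(
                            dur_b, f"{path}: record {rec_no}")
                    else:
                        onset_b, duration = stamp, 0.0
                    onset = _parse_tal_number(onset_b, f"{path}: record {rec_no}")
                    for text in fields[1:]:
                        if text:
                            out.append((text.decode("utf-8"), onset, duration))
    return out
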