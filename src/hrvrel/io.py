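"""Read and write RR-interval recordings in the Polar-export text dialect.

Polar Flow exports interbeat intervals as a whitespace-delimited ``.txt``
file, one interval in milliseconds per token. The reader accepts any
whitespace (space, tab, newline); the writer emits the canonical
one-value-per-line form so round-trips are byte-stable.
"""

from __future__ import annotations

import io as _io
from os import PathLike
from typing import TextIO, Union

import numpy as np

from .series import RRiSeries

TextSource = Union[str, PathLike, TextIO]


def _tokens(source: TextSource) -> tuple[list[str], bool]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    return text.split(), isinstance(text, str)


def read_rri_txt(source: TextSource, skip_header: bool = False) -> RRiSeries:
    """Parse a whitespace-delimited RRi text file into an :class:`RRiSeries`.

    Parameters
    ----------
    source : path or open text stream
    skip_header : bool
        If true, leading non-numeric lines are skipped (some exports carry
        a header); otherwise any non-numeric token is an error.

    Raises
    ------
    ValueError
        On an empty file, a non-numeric token (named with its 1-based
        position), or a non-positive interval.
    """
    toks, _ = _tokens(source)
    if skip_header:
        start = 0
        for start, tok in enumerate(toks):
            try:
                float(tok)
                break
            except ValueError:
                continue
        else:
            start = len(toks)
        toks = toks[start:]
    if not toks:
        raise ValueError("no intervals")
    values = np.empty(len(toks))
    for i, tok in enumerate(toks):
        try:
            values[i] = float(tok)
        except ValueError:
            raise ValueError(
                f"non-numeric token {tok!r} at position {i + 1}"
            ) from None
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValueError(f"non-finite interval at position {bad + 1}")
    if np.any(values <= 0):
        bad = int(np.flatnonzero(values <= 0)[0])
        raise ValueError(
            f"non-positive interval {values[bad]} ms at position {bad + 1}"
        )
    return RRiSeries(values)


def write_rri_txt(series: RRiSeries, sink: TextSource) -> None:
    """Write ``series`` as one interval per line, in ms.

    Integers are written without a decimal point so that integer-valued
    exports round-trip byte-identically; fractional values keep full
    ``repr`` precision.
    """
    if len(series) == 0:  # pragma: no cover - RRiSeries forbids empty
        raise ValueError("empty series")
    lines = []
    for v in series.intervals:
        lines.append(str(int(v)) if float(v).is_integer() else repr(float(v)))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def dumps(series: RRiSeries) -> str:
    """Return the canonical text form of ``series``."""
    buf = _io.StringIO()
    write_rri_txt(series, buf)
    return buf.getvalue()


def loads(text: str) -> RRiSeries:
    """Parse an RRi series from a string."""
    return read_rri_txt(_io.StringIO(text))
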