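"""Minimal FCS 3.1 writer for integrated-parameter export.

Only list-mode float32 data with the keywords conventional cytometry
software needs ($DATATYPE F, $MODE L, little-endian $BYTEORD, linear
$PnE).  Reading FCS is out of scope for this package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_fcs"]

_DELIM = "/"
_HEADER_LEN = 58


def _text_segment(params, n_events, data_begin, data_end) -> bytes:
    keywords = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        # Zero-padded to fixed width so the segment length does not depend
        # on the offset values themselves.
        ("$BEGINDATA", f"{data_begin:010d}"),
        ("$ENDDATA", f"{data_end:010d}"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(len(params))),
        ("$TOT", str(n_events)),
    ]
    for i, name in enumerate(params, start=1):
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", "262144"),
        ]
    body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in keywords) + _DELIM
    return body.encode("ascii")


def write_fcs(path, params: list[str], data: np.ndarray) -> None:
    """Write ``data`` (n_events x n_params, cast to little-endian float32)
    as an FCS 3.1 file with parameter short names ``params``."""
    data = np.ascontiguousarray(np.asarray(data, dtype="<f4"))
    if data.ndim != 2 or data.shape[1] != len(params):
        raise ValueError("data must be 2-D with one column per parameter")
    n_events = data.shape[0]

    # Two-pass offset computation: text length is independent of the
    # offsets because they are written zero-padded.
    text = _text_segment(params, n_events, 0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1 if n_events else 0
    if n_events == 0:
        data_begin = 0
    text = _text_segment(params, n_events, data_begin, data_end)

    header = b"FCS3.1    "
    for offset in (text_begin, text_end,
                   data_begin if data_begin <= 99999999 else 0,
                   data_end if data_end <= 99999999 else 0,
                   0, 0):
        header += f"{offset:>8d}".encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
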