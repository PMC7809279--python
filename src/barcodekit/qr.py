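"""Minimal QR code (model 2) encoder with a structural self-decoder.

Implements the standard byte-mode symbol construction for versions 1-10
at error-correction level M: Reed-Solomon block coding over GF(256)
(primitive polynomial 0x11d), the fixed function patterns, the
two-column zigzag data placement, the eight data masks with the standard
penalty scoring, and the BCH-protected format/version information.

The module also contains :func:`decode_matrix`, which reads one of our
own clean matrices back (locate mask from the format information,
unmask, deinterleave, verify the Reed-Solomon syndromes are zero and
parse the byte segment). It is a structural self-test for symbols this
module produced, not a general-purpose camera-image decoder.

Everything is deterministic: the same payload always yields the same
matrix and the same PNG bytes.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# GF(256) arithmetic
# ---------------------------------------------------------------------------

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _rs_generator(n_ec: int) -> list[int]:
    g = [1]
    for i in range(n_ec):
        g2 = [0] * (len(g) + 1)
        for j, c in enumerate(g):
            g2[j] ^= _gf_mul(c, 1)
            g2[j + 1] ^= _gf_mul(c, _EXP[i])
        g = g2
    return g


def _rs_ec_codewords(data: list[int], n_ec: int) -> list[int]:
    gen = _rs_generator(n_ec)
    rem = list(data) + [0] * n_ec
    for i in range(len(data)):
        factor = rem[i]
        if factor:
            for j, g in enumerate(gen):
                rem[i + j] ^= _gf_mul(g, factor)
    return rem[len(data):]


def _rs_syndromes_zero(codewords: list[int], n_ec: int) -> bool:
    for i in range(n_ec):
        x = _EXP[i]
        acc = 0
        for c in codewords:
            acc = _gf_mul(acc, x) ^ c
        if acc != 0:
            return False
    return True


# ---------------------------------------------------------------------------
# Version tables (EC level M)
# ---------------------------------------------------------------------------

#: version -> (ec codewords per block, [(block count, data codewords), ...])
_BLOCKS_M = {
    1: (10, [(1, 16)]),
    2: (16, [(1, 28)]),
    3: (26, [(1, 44)]),
    4: (18, [(2, 32)]),
    5: (24, [(2, 43)]),
    6: (16, [(4, 27)]),
    7: (18, [(4, 31)]),
    8: (22, [(2, 38), (2, 39)]),
    9: (22, [(3, 36), (2, 37)]),
    10: (26, [(4, 43), (1, 44)]),
}

_ALIGN_POS = {
    1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30], 6: [6, 34],
    7: [6, 22, 38], 8: [6, 24, 42], 9: [6, 26, 46], 10: [6, 28, 50],
}

_EC_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}


class QRCapacityError(ValueError):
    """Payload exceeds the byte capacity of the supported versions."""


def _data_capacity(version: int) -> int:
    _, groups = _BLOCKS_M[version]
    return sum(cnt * dc for cnt, dc in groups)


def byte_capacity(version: int) -> int:
    """Maximum byte-mode payload length for the version at level M."""
    count_bits = 8 if version <= 9 else 16
    return (_data_capacity(version) * 8 - 4 - count_bits) // 8


def _choose_version(n_bytes: int) -> int:
    for v in range(1, 11):
        if n_bytes <= byte_capacity(v):
            return v
    raise QRCapacityError(
        f"payload of {n_bytes} bytes exceeds version-10/M capacity "
        f"({byte_capacity(10)} bytes); use a shorter window"
    )


def _encode_data(payload: bytes, version: int) -> list[int]:
    bits: list[int] = []

    def push(value: int, width: int) -> None:
        for b in range(width - 1, -1, -1):
            bits.append((value >> b) & 1)

    push(0b0100, 4)  # byte mode
    push(len(payload), 8 if version <= 9 else 16)
    for byte in payload:
        push(byte, 8)
    total_bits = _data_capacity(version) * 8
    bits.extend([0] * min(4, total_bits - len(bits)))  # terminator
    bits.extend([0] * ((8 - len(bits) % 8) % 8))
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    pad = [0xEC, 0x11]
    i = 0
    while len(codewords) < _data_capacity(version):
        codewords.append(pad[i % 2])
        i += 1
    return codewords


def _interleave(codewords: list[int], version: int) -> list[int]:
    n_ec, groups = _BLOCKS_M[version]
    blocks: list[list[int]] = []
    pos = 0
    for cnt, dc in groups:
        for _ in range(cnt):
            blocks.append(codewords[pos:pos + dc])
            pos += dc
    ec_blocks = [_rs_ec_codewords(b, n_ec) for b in blocks]
    out: list[int] = []
    for i in range(max(len(b) for b in blocks)):
        for b in blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(n_ec):
        for eb in ec_blocks:
            out.append(eb[i])
    return out


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _function_mask(version: int) -> np.ndarray:
    """Boolean matrix marking module positions reserved for function
    patterns and format/version information."""
    size = 17 + 4 * version
    f = np.zeros((size, size), dtype=bool)
    for r0, c0 in ((0, 0), (0, size - 7), (size - 7, 0)):
        f[max(r0 - 1, 0):r0 + 8, max(c0 - 1, 0):c0 + 8] = True
    f[6, :] = True
    f[:, 6] = True
    for r in _ALIGN_POS[version]:
        for c in _ALIGN_POS[version]:
            # skip alignment patterns overlapping finder corners
            if (r < 9 and c < 9) or (r < 9 and c > size - 10) or \
               (r > size - 10 and c < 9):
                continue
            f[r - 2:r + 3, c - 2:c + 3] = True
    # format info strips
    f[8, :9] = True
    f[:9, 8] = True
    f[8, size - 8:] = True
    f[size - 8:, 8] = True
    if version >= 7:
        f[:6, size - 11:size - 8] = True
        f[size - 11:size - 8, :6] = True
    return f


def _place_fixed(version: int) -> np.ndarray:
    size = 17 + 4 * version
    m = np.zeros((size, size), dtype=bool)

    def finder(r0: int, c0: int) -> None:
        m[r0:r0 + 7, c0:c0 + 7] = True
        m[r0 + 1:r0 + 6, c0 + 1:c0 + 6] = False
        m[r0 + 2:r0 + 5, c0 + 2:c0 + 5] = True

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)
    for j in range(8, size - 8):
        m[6, j] = j % 2 == 0
        m[j, 6] = j % 2 == 0
    for r in _ALIGN_POS[version]:
        for c in _ALIGN_POS[version]:
            if (r < 9 and c < 9) or (r < 9 and c > size - 10) or \
               (r > size - 10 and c < 9):
                continue
            m[r - 2:r + 3, c - 2:c + 3] = True
            m[r - 1:r + 2, c - 1:c + 2] = False
            m[r, c] = True
    m[size - 8, 8] = True  # dark module
    return m


def _data_coordinates(version: int) -> list[tuple[int, int]]:
    """The zigzag module order used for data bits."""
    size = 17 + 4 * version
    reserved = _function_mask(version)
    coords: list[tuple[int, int]] = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for r in rows:
            for c in (col, col - 1):
                if not reserved[r, c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


_MASK_FN = [
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
]


def _bch_format(ec: str, mask: int) -> int:
    data = (_EC_BITS[ec] << 3) | mask
    rem = data << 10
    gen = 0b10100110111
    for i in range(14, 9, -1):
        if rem & (1 << i):
            rem ^= gen << (i - 10)
    return ((data << 10) | rem) ^ 0b101010000010010


def _bch_version(version: int) -> int:
    rem = version << 12
    gen = 0b1111100100101
    for i in range(17, 11, -1):
        if rem & (1 << i):
            rem ^= gen << (i - 12)
    return (version << 12) | rem


def _write_format(m: np.ndarray, bits: int) -> None:
    size = m.shape[0]
    vals = [(bits >> (14 - i)) & 1 == 1 for i in range(15)]
    rc_a = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
            (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    rc_b = [(size - 1, 8), (size - 2, 8), (size - 3, 8), (size - 4, 8),
            (size - 5, 8), (size - 6, 8), (size - 7, 8),
            (8, size - 8), (8, size - 7), (8, size - 6), (8, size - 5),
            (8, size - 4), (8, size - 3), (8, size - 2), (8, size - 1)]
    for (r, c), v in zip(rc_a, vals):
        m[r, c] = v
    for (r, c), v in zip(rc_b, vals):
        m[r, c] = v


def _write_version_info(m: np.ndarray, version: int) -> None:
    if version < 7:
        return
    size = m.shape[0]
    bits = _bch_version(version)
    for i in range(18):
        v = (bits >> i) & 1 == 1
        r, c = i // 3, size - 11 + i % 3
        m[r, c] = v
        m[c, r] = v


def _penalty(m: np.ndarray) -> int:
    size = m.shape[0]
    score = 0
    # rule 1: runs >= 5
    for grid in (m, m.T):
        for line in grid:
            run = 1
            for i in range(1, size):
                if line[i] == line[i - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + run - 5
                    run = 1
            if run >= 5:
                score += 3 + run - 5
    # rule 2: 2x2 blocks
    blocks = (m[:-1, :-1] == m[1:, :-1]) & (m[:-1, :-1] == m[:-1, 1:]) & \
             (m[:-1, :-1] == m[1:, 1:])
    score += 3 * int(blocks.sum())
    # rule 3: finder-like patterns
    pat = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
    for grid in (m, m.T):
        for line in grid:
            arr = np.asarray(line)
            for i in range(size - 10):
                win = arr[i:i + 11]
                if np.array_equal(win, pat) or np.array_equal(win, pat[::-1]):
                    score += 40
    # rule 4: dark proportion
    pct = 100.0 * m.sum() / m.size
    score += 10 * int(abs(pct - 50) // 5)
    return score


def encode_matrix(payload: str, ec: str = "M") -> np.ndarray:
    """Encode text (UTF-8, byte mode) into a boolean QR module matrix."""
    if ec != "M":
        raise ValueError("only error-correction level M is implemented")
    if not payload:
        raise ValueError("empty payload")
    data = payload.encode("utf-8")
    version = _choose_version(len(data))
    stream = _interleave(_encode_data(data, version), version)
    bits = [(byte >> (7 - i)) & 1 for byte in stream for i in range(8)]
    coords = _data_coordinates(version)
    base = _place_fixed(version)

    best: tuple[int, int, np.ndarray] | None = None
    for mask in range(8):
        m = base.copy()
        for (r, c), b in zip(coords, bits):
            v = bool(b) ^ _MASK_FN[mask](r, c)
            m[r, c] = v
        # remainder modules stay 0 but still receive the mask
        for r, c in coords[len(bits):]:
            m[r, c] = _MASK_FN[mask](r, c)
        _write_format(m, _bch_format(ec, mask))
        _write_version_info(m, version)
        s = _penalty(m)
        if best is None or s < best[0]:
            best = (s, mask, m)
    return best[2]


# ---------------------------------------------------------------------------
# Structural self-decoder
# ---------------------------------------------------------------------------

def decode_matrix(m: np.ndarray) -> str:
    """Decode a clean module matrix produced by :func:`encode_matrix`."""
    size = m.shape[0]
    version = (size - 17) // 4
    if version not in _BLOCKS_M:
        raise ValueError(f"unsupported matrix size {size}")
    fmt = 0
    rc_a = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
            (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    for r, c in rc_a:
        fmt = (fmt << 1) | int(m[r, c])
    fmt ^= 0b101010000010010
    mask = (fmt >> 10) & 0b111
    if (fmt >> 13) != _EC_BITS["M"]:
        raise ValueError("unexpected error-correction level")

    coords = _data_coordinates(version)
    bits = [int(m[r, c]) ^ int(_MASK_FN[mask](r, c)) for r, c in coords]
    n_ec, groups = _BLOCKS_M[version]
    n_blocks = sum(cnt for cnt, _ in groups)
    total = _data_capacity(version) + n_ec * n_blocks
    stream = [
        int("".join(map(str, bits[i * 8:(i + 1) * 8])), 2) for i in range(total)
    ]

    # de-interleave
    sizes = [dc for cnt, dc in groups for _ in range(cnt)]
    blocks: list[list[int]] = [[] for _ in sizes]
    it = iter(stream[:_data_capacity(version)])
    for i in range(max(sizes)):
        for bi, sz in enumerate(sizes):
            if i < sz:
                blocks[bi].append(next(it))
    ec_stream = stream[_data_capacity(version):]
    ec_blocks: list[list[int]] = [[] for _ in sizes]
    it2 = iter(ec_stream)
    for i in range(n_ec):
        for bi in range(n_blocks):
            ec_blocks[bi].append(next(it2))
    for b, eb in zip(blocks, ec_blocks):
        if not _rs_syndromes_zero(b + eb, n_ec):
            raise ValueError("Reed-Solomon check failed")

    data = [cw for b in blocks for cw in b]
    bitstr = "".join(f"{cw:08b}" for cw in data)
    if bitstr[:4] != "0100":
        raise ValueError("not a byte-mode symbol")
    cb = 8 if version <= 9 else 16
    count = int(bitstr[4:4 + cb], 2)
    start = 4 + cb
    payload = bytes(
        int(bitstr[start + 8 * i:start + 8 * (i + 1)], 2) for i in range(count)
    )
    return payload.decode("utf-8")


def render_png(matrix: np.ndarray, path, scale: int = 8, border: int = 4) -> None:
    """Write the module matrix as a black-on-white PNG (deterministic)."""
    from PIL import Image

    size = matrix.shape[0]
    canvas = np.ones((size + 2 * border, size + 2 * border), dtype=np.uint8) * 255
    canvas[border:border + size, border:border + size] = np.where(matrix, 0, 255)
    img = Image.fromarray(
        np.repeat(np.repeat(canvas, scale, axis=0), scale, axis=1), mode="L"
    )
    img.save(str(path), format="PNG")
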