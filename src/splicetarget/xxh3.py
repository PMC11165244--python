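"""Pure-Python XXH3 128-bit hash (unseeded).

Implements the XXH3-128 algorithm with the default secret, as published in
the xxHash format specification.  Only the seed-0 variant is provided, which
is all the package needs to derive stable context-sequence identifiers.
Digests are returned in canonical (big-endian, high||low) hex form and match
reference implementations byte for byte; a frozen vector suite in the tests
pins this against an independent implementation.

Not optimised for throughput: inputs here are short (hundreds of bytes).
"""

from __future__ import annotations

import struct

_MASK64 = 0xFFFFFFFFFFFFFFFF

_PRIME32_1 = 0x9E3779B1
_PRIME32_2 = 0x85EBCA77
_PRIME32_3 = 0xC2B2AE3D
_PRIME64_1 = 0x9E3779B185EBCA87
_PRIME64_2 = 0xC2B2AE3D27D4EB4F
_PRIME64_3 = 0x165667B19E3779F9
_PRIME64_4 = 0x85EBCA77C2B2AE63
_PRIME64_5 = 0x27D4EB2F165667C5
_PRIME_MX1 = 0x165667919E3779F9
_PRIME_MX2 = 0x9FB21C651E98DF25

# 192-byte default secret of the XXH3 specification.
_SECRET = bytes.fromhex(
    "b8fe6c3923a44bbe7c01812cf721ad1c"
    "ded46de9839097db7240a4a4b7b3671f"
    "cb79e64eccc0e578825ad07dccff7221"
    "b8084674f743248ee03590e6813a264c"
    "3c2852bb91c300cb88d0658b1b532ea3"
    "71644897a20df94e3819ef46a9deacd8"
    "a8fa763fe39c343ff9dcbbc7c70b4f1d"
    "8a51e04bcdb45931c89f7ec9d9787364"
    "eac5ac8334d3ebc3c581a0fffa1363eb"
    "170ddd51b7f0da49d316552629d4689e"
    "2b16be587d47a1fc8ff8b8d17ad031ce"
    "45cb3a8f95160428afd7fbcabb4b407e"
)


def _read64(buf: bytes, off: int) -> int:
    return struct.unpack_from("<Q", buf, off)[0]


def _read32(buf: bytes, off: int) -> int:
    return struct.unpack_from("<I", buf, off)[0]


def _swap32(x: int) -> int:
    return struct.unpack("<I", struct.pack(">I", x))[0]


def _swap64(x: int) -> int:
    return struct.unpack("<Q", struct.pack(">Q", x))[0]


def _rotl32(x: int, r: int) -> int:
    return ((x << r) | (x >> (32 - r))) & 0xFFFFFFFF


def _mul128(a: int, b: int) -> tuple[int, int]:
    p = a * b
    return p & _MASK64, (p >> 64) & _MASK64


def _mul128_fold64(a: int, b: int) -> int:
    lo, hi = _mul128(a, b)
    return lo ^ hi


def _avalanche(h: int) -> int:
    h &= _MASK64
    h ^= h >> 37
    h = (h * _PRIME_MX1) & _MASK64
    h ^= h >> 32
    return h


def _avalanche64(h: int) -> int:
    h &= _MASK64
    h ^= h >> 33
    h = (h * _PRIME64_2) & _MASK64
    h ^= h >> 29
    h = (h * _PRIME64_3) & _MASK64
    h ^= h >> 32
    return h


def _len_0(secret: bytes) -> tuple[int, int]:
    lo = _avalanche64(_read64(secret, 64) ^ _read64(secret, 72))
    hi = _avalanche64(_read64(secret, 80) ^ _read64(secret, 88))
    return lo, hi


def _len_1to3(data: bytes, secret: bytes) -> tuple[int, int]:
    n = len(data)
    c1, c2, c3 = data[0], data[n >> 1], data[n - 1]
    combined_lo = (c1 << 16) | (c2 << 24) | c3 | (n << 8)
    combined_hi = _rotl32(_swap32(combined_lo), 13)
    bitflip_lo = (_read32(secret, 0) ^ _read32(secret, 4)) & _MASK64
    bitflip_hi = (_read32(secret, 8) ^ _read32(secret, 12)) & _MASK64
    return (
        _avalanche64(combined_lo ^ bitflip_lo),
        _avalanche64(combined_hi ^ bitflip_hi),
    )


def _len_4to8(data: bytes, secret: bytes) -> tuple[int, int]:
    n = len(data)
    input_lo = _read32(data, 0)
    input_hi = _read32(data, n - 4)
    input64 = input_lo + (input_hi << 32)
    bitflip = _read64(secret, 16) ^ _read64(secret, 24)
    keyed = input64 ^ bitflip
    lo, hi = _mul128(keyed, (_PRIME64_1 + (n << 2)) & _MASK64)
    hi = (hi + (lo << 1)) & _MASK64
    lo ^= hi >> 3
    lo ^= lo >> 35
    lo = (lo * _PRIME_MX2) & _MASK64
    lo ^= lo >> 28
    hi = _avalanche(hi)
    return lo, hi


def _len_9to16(data: bytes, secret: bytes) -> tuple[int, int]:
    n = len(data)
    bitflip_lo = _read64(secret, 32) ^ _read64(secret, 40)
    bitflip_hi = _read64(secret, 48) ^ _read64(secret, 56)
    input_lo = _read64(data, 0)
    input_hi = _read64(data, n - 8)
    m_lo, m_hi = _mul128(input_lo ^ input_hi ^ bitflip_lo, _PRIME64_1)
    m_lo = (m_lo + ((n - 1) << 54)) & _MASK64
    input_hi ^= bitflip_hi
    m_hi = (
        m_hi + input_hi + (input_hi & 0xFFFFFFFF) * (_PRIME32_2 - 1)
    ) & _MASK64
    m_lo ^= _swap64(m_hi)
    h_lo, h_hi = _mul128(m_lo, _PRIME64_2)
    h_hi = (h_hi + m_hi * _PRIME64_2) & _MASK64
    return _avalanche(h_lo), _avalanche(h_hi)


def _mix16(data: bytes, doff: int, secret: bytes, soff: int) -> int:
    return _mul128_fold64(
        _read64(data, doff) ^ _read64(secret, soff),
        _read64(data, doff + 8) ^ _read64(secret, soff + 8),
    )


def _mix32(
    acc: tuple[int, int], data: bytes, off1: int, off2: int, secret: bytes, soff: int
) -> tuple[int, int]:
    lo, hi = acc
    lo = (lo + _mix16(data, off1, secret, soff)) & _MASK64
    lo ^= (_read64(data, off2) + _read64(data, off2 + 8)) & _MASK64
    hi = (hi + _mix16(data, off2, secret, soff + 16)) & _MASK64
    hi ^= (_read64(data, off1) + _read64(data, off1 + 8)) & _MASK64
    return lo, hi


def _finalize_mid(acc: tuple[int, int], n: int) -> tuple[int, int]:
    lo = (acc[0] + acc[1]) & _MASK64
    hi = (
        acc[0] * _PRIME64_1 + acc[1] * _PRIME64_4 + n * _PRIME64_2
    ) & _MASK64
    lo = _avalanche(lo)
    hi = (0 - _avalanche(hi)) & _MASK64
    return lo, hi


def _len_17to128(data: bytes, secret: bytes) -> tuple[int, int]:
    n = len(data)
    acc = ((n * _PRIME64_1) & _MASK64, 0)
    if n > 96:
        acc = _mix32(acc, data, 48, n - 64, secret, 96)
    if n > 64:
        acc = _mix32(acc, data, 32, n - 48, secret, 64)
    if n > 32:
        acc = _mix32(acc, data, 16, n - 32, secret, 32)
    acc = _mix32(acc, data, 0, n - 16, secret, 0)
    return _finalize_mid(acc, n)


def _len_129to240(data: bytes, secret: bytes) -> tuple[int, int]:
    n = len(data)
    acc = ((n * _PRIME64_1) & _MASK64, 0)
    for i in range(4):
        acc = _mix32(acc, data, 32 * i, 32 * i + 16, secret, 32 * i)
    acc = (_avalanche(acc[0]), _avalanche(acc[1]))
    for i in range(4, n // 32):
        acc = _mix32(acc, data, 32 * i, 32 * i + 16, secret, 3 + 32 * (i - 4))
    acc = _mix32(acc, data, n - 16, n - 32, secret, 136 - 17 - 16)
    return _finalize_mid(acc, n)


def _accumulate512(acc: list[int], data: bytes, doff: int, secret: bytes, soff: int) -> None:
    for i in range(8):
        val = _read64(data, doff + 8 * i)
        key = val ^ _read64(secret, soff + 8 * i)
        acc[i ^ 1] = (acc[i ^ 1] + val) & _MASK64
        acc[i] = (acc[i] + (key & 0xFFFFFFFF) * (key >> 32)) & _MASK64


def _scramble(acc: list[int], secret: bytes, soff: int) -> None:
    for i in range(8):
        a = acc[i]
        a ^= a >> 47
        a ^= _read64(secret, soff + 8 * i)
        acc[i] = (a * _PRIME32_1) & _MASK64


def _merge_accs(acc: list[int], secret: bytes, soff: int, start: int) -> int:
    result = start
    for i in range(4):
        result = (
            result
            + _mul128_fold64(
                acc[2 * i] ^ _read64(secret, soff + 16 * i),
                acc[2 * i + 1] ^ _read64(secret, soff + 16 * i + 8),
            )
        ) & _MASK64
    return _avalanche(result)


def _len_long(data: bytes, secret: bytes) -> tuple[int, int]:
    n = len(data)
    acc = [
        _PRIME32_3,
        _PRIME64_1,
        _PRIME64_2,
        _PRIME64_3,
        _PRIME64_4,
        _PRIME32_2,
        _PRIME64_5,
        _PRIME32_1,
    ]
    stripes_per_block = (len(secret) - 64) // 8  # 16
    block_len = 64 * stripes_per_block
    n_blocks = (n - 1) // block_len
    for b in range(n_blocks):
        for s in range(stripes_per_block):
            _accumulate512(acc, data, b * block_len + 64 * s, secret, 8 * s)
        _scramble(acc, secret, len(secret) - 64)
    n_stripes = ((n - 1) - block_len * n_blocks) // 64
    for s in range(n_stripes):
        _accumulate512(acc, data, n_blocks * block_len + 64 * s, secret, 8 * s)
    _accumulate512(acc, data, n - 64, secret, len(secret) - 64 - 7)
    lo = _merge_accs(acc, secret, 11, (n * _PRIME64_1) & _MASK64)
    hi = _merge_accs(
        acc, secret, len(secret) - 64 - 11, (~(n * _PRIME64_2)) & _MASK64
    )
    return lo, hi


def xxh3_128_digest(data: bytes) -> tuple[int, int]:
    """Return the (low64, high64) XXH3-128 words of ``data`` (seed 0)."""
    n = len(data)
    if n == 0:
        return _len_0(_SECRET)
    if n <= 3:
        return _len_1to3(data, _SECRET)
    if n <= 8:
        return _len_4to8(data, _SECRET)
    if n <= 16:
        return _len_9to16(data, _SECRET)
    if n <= 128:
        return _len_17to128(data, _SECRET)
    if n <= 240:
        return _len_129to240(data, _SECRET)
    return _len_long(data, _SECRET)


def xxh3_128_hexdigest(data: bytes | str) -> str:
    """Canonical 32-character lowercase hex digest (big-endian high||low)."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    lo, hi = xxh3_128_digest(data)
    return f"{hi:016x}{lo:016x}"
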