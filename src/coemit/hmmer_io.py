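"""Read and write profile HMMs in the HMMER3 text format.

The HMMER3 ``.hmm`` format stores probabilities as negative natural
logarithms in 5-decimal fixed point, with the token ``*`` standing for
probability zero (log-space infinity).  A file may concatenate any number
of models, each terminated by ``//``.  Text dialects ``3/b`` through
``3/f`` are accepted (all public protein databases ship >= 3/b); ``3/a``
and binary files are rejected.
"""

from __future__ import annotations

import math
import re
from typing import IO, Iterable, Iterator

import numpy as np

from .model import N_AA, ProfileHMM, default_background

_SUPPORTED_DIALECTS = "bcdef"
_HEADER_RE = re.compile(r"^HMMER3/([a-z])\b")

# Header keys whose values are kept verbatim in metadata.
_PASSTHROUGH_KEYS = {
    "ACC", "DESC", "MAXL", "RF", "MM", "CONS", "CS", "MAP", "DATE", "COM",
    "NSEQ", "EFFN", "CKSUM", "GA", "TC", "NC", "BM", "SM",
}


class FormatError(ValueError):
    """The input is not valid HMMER3 text of a supported dialect."""


class UnsupportedAlphabetError(FormatError):
    """The model is not an amino-acid profile."""


def _decode(token: str) -> float:
    """Negative-natural-log field -> probability; '*' -> exactly 0."""
    if token == "*":
        return 0.0
    return math.exp(-float(token))


def _encode(p: float) -> str:
    """Probability -> 9-char negative-natural-log field; 0 -> '*'."""
    if p <= 0.0:
        return "      *"
    return f"{-math.log(p):7.5f}"


def _open_text(path_or_stream, mode: str) -> tuple[IO[str], bool]:
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(path_or_stream, mode), True


def read_hmmer3(path_or_stream) -> list[ProfileHMM]:
    """Parse one or more concatenated HMMER3 text models.

    Returns a list of :class:`ProfileHMM` with all fields converted to
    linear probabilities.  The ``COMPO`` average-composition line, when
    present, is stored in metadata and used as the model background.

    Raises
    ------
    FormatError
        On a non-HMMER3 header, an unsupported dialect, or a node count
        that disagrees with the ``LENG`` header.
    UnsupportedAlphabetError
        For DNA/RNA or other non-amino profiles.
    """
    stream, close = _open_text(path_or_stream, "r")
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()
    models = []
    it: Iterator[str] = iter(lines)
    for line in it:
        if not line.strip():
            continue
        m = _HEADER_RE.match(line)
        if not m:
            raise FormatError(f"not a HMMER3 model header: {line[:40]!r}")
        dialect = m.group(1)
        if dialect not in _SUPPORTED_DIALECTS:
            raise FormatError(
                f"unsupported HMMER3 dialect 3/{dialect}; supported: 3/b-3/f"
            )
        models.append(_read_model(it, line.strip(), dialect))
    return models


def _read_model(it: Iterator[str], header: str, dialect: str) -> ProfileHMM:
    meta: dict = {"FORMAT": header, "DIALECT": dialect}
    name = None
    leng = None
    # --- header section -------------------------------------------------
    for line in it:
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0]
        if key == "HMM":
            break
        value = line[len(key):].strip()
        if key == "NAME":
            name = value
        elif key == "LENG":
            leng = int(value)
        elif key == "ALPH":
            meta["ALPH"] = value.lower()
            if value.lower() != "amino":
                raise UnsupportedAlphabetError(
                    f"model {name!r}: unsupported alphabet {value!r} (amino only)"
                )
        elif key == "STATS":
            meta.setdefault("STATS", []).append(value)
        elif key in _PASSTHROUGH_KEYS:
            meta[key] = value
        else:
            meta.setdefault("EXTRA", {})[key] = value
    else:
        raise FormatError("truncated model: no HMM line")
    if name is None:
        raise FormatError("model without NAME header")
    if leng is None:
        raise FormatError(f"model {name!r}: missing LENG header")
    if "ALPH" not in meta:
        raise UnsupportedAlphabetError(f"model {name!r}: missing ALPH header")
    next(it)  # transition label line

    match_rows: list[list[float]] = []
    insert_rows: list[list[float]] = []
    trans_rows: list[list[float]] = []
    node_annot: list[list[str]] = []
    compo = None
    background = None

    first = next(it).split()
    if first and first[0] == "COMPO":
        compo = [_decode(t) for t in first[1 : 1 + N_AA]]
        meta["COMPO"] = np.array(compo)
        background = np.array(compo)
        first = next(it).split()
    # node 0: insert emissions + BEGIN transitions
    insert0 = [_decode(t) for t in first[:N_AA]]
    trans_rows.append([_decode(t) for t in next(it).split()[:7]])

    node = 0
    for line in it:
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "//":
            break
        node += 1
        try:
            idx = int(tokens[0])
        except ValueError as exc:
            raise FormatError(
                f"model {name!r}: expected node index at node {node}: "
                f"{tokens[0]!r}"
            ) from exc
        if idx != node:
            raise FormatError(
                f"model {name!r}: corrupt file, node {node} labelled {idx}"
            )
        match_rows.append([_decode(t) for t in tokens[1 : 1 + N_AA]])
        node_annot.append(tokens[1 + N_AA :])
        insert_rows.append([_decode(t) for t in next(it).split()[:N_AA]])
        trans_rows.append([_decode(t) for t in next(it).split()[:7]])
    else:
        raise FormatError(f"model {name!r}: missing // terminator")

    if node != leng:
        raise FormatError(
            f"model {name!r}: corrupt file, LENG {leng} but {node} nodes read"
        )
    meta["INSERT0"] = np.array(insert0)
    if node_annot and any(a for a in node_annot):
        meta["NODE_ANNOT"] = node_annot
    model = ProfileHMM(
        name=name,
        match_emissions=np.array(match_rows),
        insert_emissions=np.array(insert_rows),
        transitions=np.array(trans_rows),
        background=background if background is not None else default_background(),
        metadata=meta,
    )
    return model.validate(tol=1e-4)


# ---------------------------------------------------------------------------
# writing

_TR_HEADER = (
    "            m->m     m->i     m->d     i->m     i->i     d->m     d->d"
)


def write_hmmer3(models: Iterable[ProfileHMM], path_or_stream) -> None:
    """Serialize models as HMMER3/f-dialect text.

    Each model is validated before any bytes are emitted; zero
    probabilities become ``*``, everything else 5-decimal negative natural
    logs.  An empty model list writes an empty file.
    """
    models = list(models)
    for m in models:
        m.validate(tol=1e-4)
    stream, close = _open_text(path_or_stream, "w")
    try:
        for m in models:
            _write_model(m, stream)
    finally:
        if close:
            stream.close()


def _fields(values) -> str:
    return "  ".join(_encode(v) for v in values)


def _write_model(m: ProfileHMM, out: IO[str]) -> None:
    L = m.length
    out.write("HMMER3/f [coemit | profile HMM text]\n")
    out.write(f"NAME  {m.name}\n")
    for key in ("ACC", "DESC"):
        if key in m.metadata:
            out.write(f"{key}   {m.metadata[key]}\n")
    out.write(f"LENG  {L}\n")
    out.write("ALPH  amino\n")
    for key in ("RF", "MM", "CONS", "CS", "MAP"):
        out.write(f"{key.ljust(5)} {m.metadata.get(key, 'no')}\n")
    for key in ("NSEQ", "EFFN", "CKSUM"):
        if key in m.metadata:
            out.write(f"{key.ljust(5)} {m.metadata[key]}\n")
    out.write("HMM          A        C        D        E        F        G"
              "        H        I        K        L        M        N"
              "        P        Q        R        S        T        V"
              "        W        Y\n")
    out.write(_TR_HEADER + "\n")
    compo = m.metadata.get("COMPO")
    if compo is not None:
        out.write(f"  COMPO   {_fields(compo)}\n")
    insert0 = m.metadata.get("INSERT0")
    if insert0 is None:
        insert0 = m.insert_emissions[0]
    out.write(f"          {_fields(insert0)}\n")
    out.write(f"          {_fields(m.transitions[0])}\n")
    annots = m.metadata.get("NODE_ANNOT")
    for k in range(L):
        if annots is not None and k < len(annots) and annots[k]:
            annot = " ".join(annots[k])
        else:
            annot = f"{k + 1} - - - -"
        out.write(f"{k + 1:7d}   {_fields(m.match_emissions[k])}{'':6}{annot}\n")
        out.write(f"          {_fields(m.insert_emissions[k])}\n")
        out.write(f"          {_fields(m.transitions[k + 1])}\n")
    out.write("//\n")
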