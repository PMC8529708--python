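"""Reading and writing LVC model files.

Two equivalent on-disk representations are supported:

* a human-oriented plain-text block format (``*.lvc``)::

      LVC v1
      modes 2
        1  500.0          nu1
        2  1200.0         nu2
      states 2
        1  S0  S=0  MS=0  group=sing
        2  S1  S=0  MS=0  group=sing
      epsilon
        2  0.1
      kappa
        2  1  0.005
      lambda
        1  2  1  0.002
      eta
        1  2  1.2e-4  -3e-5
      end

  Frequencies are in cm^-1; every other number is in Hartree.  Indices
  are 1-based.  ``epsilon`` holds vertical excitation energies, ``kappa``
  entries are (state, mode, value), ``lambda`` entries
  (state, state, mode, value) and ``eta`` entries
  (state, state, Re, Im).  Omitted entries are zero.

* a JSON document (``*.json``) with the same content as nested lists.

Numeric fields are written with 12 significant digits; write -> read ->
write reproduces the file byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import units
from .model import BasisSpec, ElectronicState, LVCModel, ModeSet

__all__ = ["read_model", "write_model", "model_to_dict", "model_from_dict",
           "ModelParseError"]

_FMT = "%.12g"


class ModelParseError(ValueError):
    """Raised with a line number when a model file is malformed."""


def _fmt(x: float) -> str:
    return _FMT % x


def model_to_dict(model: LVCModel) -> dict:
    """JSON-serializable dictionary form of a model."""
    d = {
        "format": "lvcdyn-model",
        "version": 1,
        "frequencies_cm1": [float(_fmt(w)) for w in
                            units.hartree_to_cm1(model.omega)],
        "mode_labels": list(model.modes.labels),
        "states": [
            {"label": s.label, "spin": s.spin, "ms": s.ms, "group": s.group}
            for s in model.basis.states
        ],
        "E": [float(_fmt(e)) for e in model.E],
        "kappa": model.kappa.tolist(),
        "lambda": model.lam.tolist(),
        "eta_re": model.eta.real.tolist(),
        "eta_im": model.eta.imag.tolist(),
    }
    if model.gamma is not None:
        d["gamma"] = model.gamma.tolist()
    return d


def model_from_dict(d: dict) -> LVCModel:
    if d.get("format") != "lvcdyn-model":
        raise ModelParseError("not an lvcdyn model document")
    modes = ModeSet(
        frequencies=units.cm1_to_hartree(np.asarray(d["frequencies_cm1"], float)),
        labels=tuple(d.get("mode_labels", ())),
    )
    basis = BasisSpec(tuple(
        ElectronicState(s["label"], s.get("spin", 0.0), s.get("ms", 0.0),
                        s.get("group", ""))
        for s in d["states"]
    ))
    eta = np.asarray(d["eta_re"], float) + 1j * np.asarray(d["eta_im"], float)
    return LVCModel(
        modes=modes,
        basis=basis,
        E=np.asarray(d["E"], float),
        eta=eta,
        kappa=np.asarray(d["kappa"], float),
        lam=np.asarray(d["lambda"], float),
        gamma=np.asarray(d["gamma"], float) if "gamma" in d else None,
    )


def write_model(model: LVCModel, path) -> None:
    """Write a model file; format chosen by extension (.json or text)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
        return
    lines = ["LVC v1"]
    lines.append(f"modes {model.n_modes}")
    for i, (w, lbl) in enumerate(zip(units.hartree_to_cm1(model.omega),
                                     model.modes.labels)):
        lines.append(f"  {i + 1}  {_fmt(w)}  {lbl}")
    lines.append(f"states {model.n_states}")
    for i, s in enumerate(model.basis.states):
        lines.append(
            f"  {i + 1}  {s.label}  S={_fmt(s.spin)}  MS={_fmt(s.ms)}"
            f"  group={s.group or '-'}"
        )
    lines.append("epsilon")
    for i, e in enumerate(model.E):
        if e != 0.0:
            lines.append(f"  {i + 1}  {_fmt(e)}")
    lines.append("kappa")
    for n in range(model.n_states):
        for i in range(model.n_modes):
            if model.kappa[n, i] != 0.0:
                lines.append(f"  {n + 1}  {i + 1}  {_fmt(model.kappa[n, i])}")
    lines.append("lambda")
    for n in range(model.n_states):
        for m in range(n + 1, model.n_states):
            for i in range(model.n_modes):
                if model.lam[n, m, i] != 0.0:
                    lines.append(
                        f"  {n + 1}  {m + 1}  {i + 1}  {_fmt(model.lam[n, m, i])}"
                    )
    lines.append("eta")
    for n in range(model.n_states):
        for m in range(n + 1, model.n_states):
            z = model.eta[n, m]
            if z != 0:
                lines.append(f"  {n + 1}  {m + 1}  {_fmt(z.real)}  {_fmt(z.imag)}")
    if model.gamma is not None:
        lines.append("gamma")
        for n in range(model.n_states):
            for i in range(model.n_modes):
                if model.gamma[n, i] != 0.0:
                    lines.append(f"  {n + 1}  {i + 1}  {_fmt(model.gamma[n, i])}")
    lines.append("end")
    path.write_text("\n".join(lines) + "\n")


def _err(lineno: int, msg: str):
    raise ModelParseError(f"line {lineno}: {msg}")


def read_model(path) -> LVCModel:
    """Read a model file written by :func:`write_model`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return model_from_dict(json.loads(path.read_text()))
    lines = path.read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_content():
        for lineno, raw in it:
            s = raw.split("#", 1)[0].strip()
            if s:
                return lineno, s
        return None, None

    lineno, s = next_content()
    if s != "LVC v1":
        _err(lineno or 0, "missing 'LVC v1' header")

    lineno, s = next_content()
    if not (s and s.startswith("modes")):
        _err(lineno or 0, "expected 'modes <f>' block")
    f = int(s.split()[1])
    freqs = np.zeros(f)
    labels = [""] * f
    for _ in range(f):
        lineno, s = next_content()
        parts = s.split()
        i = int(parts[0]) - 1
        if not 0 <= i < f:
            _err(lineno, f"mode index {i + 1} out of range 1..{f}")
        freqs[i] = float(parts[1])
        labels[i] = parts[2] if len(parts) > 2 else f"mode{i + 1}"
    if np.any(freqs <= 0):
        _err(lineno, "all mode frequencies must be positive")

    lineno, s = next_content()
    if not (s and s.startswith("states")):
        _err(lineno or 0, "expected 'states <n>' block")
    n = int(s.split()[1])
    states: list[ElectronicState | None] = [None] * n
    for _ in range(n):
        lineno, s = next_content()
        parts = s.split()
        i = int(parts[0]) - 1
        if not 0 <= i < n:
            _err(lineno, f"state index {i + 1} out of range 1..{n}")
        label = parts[1]
        kw = {"spin": 0.0, "ms": 0.0, "group": ""}
        for p in parts[2:]:
            if p.startswith("S="):
                kw["spin"] = float(p[2:])
            elif p.startswith("MS="):
                kw["ms"] = float(p[3:])
            elif p.startswith("group="):
                kw["group"] = "" if p[6:] == "-" else p[6:]
            else:
                _err(lineno, f"unknown state attribute {p!r}")
        states[i] = ElectronicState(label, kw["spin"], kw["ms"], kw["group"])

    E = np.zeros(n)
    kappa = np.zeros((n, f))
    lam = np.zeros((n, n, f))
    eta = np.zeros((n, n), dtype=complex)
    gamma = None
    lam_seen: set[tuple[int, int, int]] = set()

    block = None
    while True:
        lineno, s = next_content()
        if s is None:
            _err(len(lines), "missing 'end' terminator")
        if s == "end":
            break
        head = s.split()[0]
        if head in ("epsilon", "kappa", "lambda", "eta", "gamma"):
            block = head
            if block == "gamma" and gamma is None:
                gamma = np.zeros((n, f))
            continue
        parts = s.split()
        try:
            if block == "epsilon":
                i = int(parts[0]) - 1
                E[i] = float(parts[1])
            elif block == "kappa":
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
                kappa[i, j] = float(parts[2])
            elif block == "lambda":
                a, b, j = int(parts[0]) - 1, int(parts[1]) - 1, int(parts[2]) - 1
                v = float(parts[3])
                if a == b:
                    _err(lineno, "lambda requires two distinct states")
                key = (min(a, b), max(a, b), j)
                if key in lam_seen and lam[a, b, j] != v:
                    _err(lineno, f"conflicting lambda entries for states "
                                 f"{a + 1},{b + 1} mode {j + 1}")
                lam_seen.add(key)
                lam[a, b, j] = lam[b, a, j] = v
            elif block == "eta":
                a, b = int(parts[0]) - 1, int(parts[1]) - 1
                if a == b:
                    _err(lineno, "eta requires two distinct states")
                z = float(parts[2]) + 1j * float(parts[3])
                if eta[a, b] != 0 and eta[a, b] != z:
                    _err(lineno, f"conflicting eta entries for states "
                                 f"{a + 1},{b + 1}")
                eta[a, b] = z
                eta[b, a] = z.conjugate()
            elif block == "gamma":
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
                gamma[i, j] = float(parts[2])
            else:
                _err(lineno, f"data before any known block: {s!r}")
        except ModelParseError:
            raise
        except (ValueError, IndexError) as exc:
            _err(lineno, f"cannot parse entry {s!r}: {exc}")

    modes = ModeSet(frequencies=units.cm1_to_hartree(freqs), labels=tuple(labels))
    return LVCModel(modes=modes, basis=BasisSpec(tuple(states)), E=E, eta=eta,
                    kappa=kappa, lam=lam, gamma=gamma)
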