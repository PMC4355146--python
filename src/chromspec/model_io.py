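"""Plain-text model files: ChromHMM-style emissions/transitions tables.

A model is written as a single tab-separated file with three sections
(transitions K x K, initial distribution, emissions over observed codes
only — rows for codes with zero probability in every state are omitted and
read back as zero) plus a JSON sidecar with metadata (K, N, marks, options).
The emission rows carry the code's mark-combination legend for readability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .spectral import HMMParams


def _combo_label(code: int, marks: list[str] | None, n_marks: int) -> str:
    present = [m for m in range(n_marks) if (code >> m) & 1]
    if marks:
        return "+".join(marks[m] for m in present) or "none"
    return "+".join(f"m{m}" for m in present) or "none"


def write_model(
    params: HMMParams,
    path,
    marks: list[str] | None = None,
    metadata: dict | None = None,
) -> None:
    path = Path(path)
    K, N = params.K, params.N
    n_marks = int(np.log2(N))
    with open(path, "w") as fh:
        fh.write(f"#states\t{K}\n#alphabet\t{N}\n")
        fh.write("#transitions (A[i,j] = P[to state i | from state j])\n")
        for i in range(K):
            fh.write("\t".join(f"{v:.10g}" for v in params.A[i]) + "\n")
        fh.write("#initial\n")
        fh.write("\t".join(f"{v:.10g}" for v in params.pi) + "\n")
        fh.write("#emissions\tcode\tcombination\tper-state probabilities\n")
        for x in range(N):
            if params.O[x].max() <= 0:
                continue
            label = _combo_label(x, marks, n_marks)
            probs = "\t".join(f"{v:.10g}" for v in params.O[x])
            fh.write(f"{x}\t{label}\t{probs}\n")
    sidecar = {
        "n_states": K,
        "alphabet_size": N,
        "marks": marks,
        **(metadata or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_model(path) -> tuple[HMMParams, dict]:
    path = Path(path)
    lines = path.read_text().splitlines()
    it = iter(lines)
    K = N = None
    A_rows: list[list[float]] = []
    pi: list[float] = []
    O = None
    section = None
    for line in it:
        if line.startswith("#states"):
            K = int(line.split("\t")[1])
        elif line.startswith("#alphabet"):
            N = int(line.split("\t")[1])
            O = np.zeros((N, K))
        elif line.startswith("#transitions"):
            section = "A"
        elif line.startswith("#initial"):
            section = "pi"
        elif line.startswith("#emissions"):
            section = "O"
        elif line.startswith("#"):
            continue
        elif section == "A":
            A_rows.append([float(v) for v in line.split("\t")])
        elif section == "pi":
            pi = [float(v) for v in line.split("\t")]
        elif section == "O":
            fields = line.split("\t")
            O[int(fields[0])] = [float(v) for v in fields[2:]]
    params = HMMParams(np.asarray(A_rows), O, np.asarray(pi))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return params, metadata
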