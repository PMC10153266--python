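"""Regenerate the cached empirical helper-curve coefficients.

Writes src/mesi/data/empirical.json: the peak-amplitude polynomials and the
boundary-ratio expansion coefficients, fitted from the analytic forward
models.  Run from the repository root.
"""
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mesi._empirical import generate_all

out = pathlib.Path(__file__).resolve().parents[1] / "src" / "mesi" / "data" / "empirical.json"
data = generate_all()
out.write_text(json.dumps(data, indent=1))
print(f"wrote {out}")
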