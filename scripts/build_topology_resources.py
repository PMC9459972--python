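"""Regenerate the bundled topology resource files from the template layout.

Run from the repository root:

    python scripts/build_topology_resources.py

The layout code in ``facesym.synthetic`` is the source of truth; this script
serialises it into ``src/facesym/resources/topology_*.json`` after running
the full FaceTopology validation.
"""

import json
from pathlib import Path

from facesym.landmarks import topology_from_dict
from facesym.synthetic import build_layout

RESOURCE_DIR = Path(__file__).resolve().parent.parent / "src" / "facesym" / "resources"
FILES = {"full_478": "topology_478.json", "compact_68": "topology_68.json"}


def main() -> None:
    for mode, filename in FILES.items():
        _, layout = build_layout(mode)
        topology_from_dict(layout)  # raises if any invariant is violated
        out = RESOURCE_DIR / filename
        out.write_text(json.dumps(layout, separators=(",", ":")) + "\n")
        print(f"wrote {out} ({out.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
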