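"""Regenerate the bundled schema data files from the curated definition.

Run from the repository root:

    python scripts/build_schema_data.py

The shipped ``src/denticode/data/denticles_v0.5.json`` is frozen output
of this script; rerunning it must reproduce the file byte-for-byte.
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from denticode.definitions import build_historical_stub, build_v05
from denticode.schema import validate_schema, write_schema_file

GROSS_TYPES = [
    "Arrowheads, Airplanes, Diamonds, and Triangles",
    "Bilateral Crowns",
    "Criss Cross",
    "Kites",
    "Many Ridged Fans and Spades",
    "Multi Dimpled Complex Polygons",
    "Petals",
    "Ridged Circles",
    "Scoops",
    "Single Dimpled Complex Polygons",
    "Smooth",
    "Spines",
    "Tridents",
    "Wedges",
    "Other Branching",
    "Other Geometric",
    "Other Linear",
    "Other Meandering",
]


def main() -> None:
    data = Path(__file__).resolve().parents[1] / "src" / "denticode" / "data"
    data.mkdir(parents=True, exist_ok=True)

    schema = build_v05()
    issues = validate_schema(schema)
    if issues:
        raise SystemExit(f"v0.5 definition fails validation: {issues}")
    write_schema_file(schema, data / "denticles_v0.5.json")
    print(f"wrote denticles_v0.5.json ({len(schema)} traits)")

    for v in ("0.1", "0.2", "0.4"):
        stub = build_historical_stub(f"denticles_v{v}")
        write_schema_file(stub, data / f"denticles_v{v}.json")
        print(f"wrote denticles_v{v}.json (historical stub)")

    (data / "gross_types.txt").write_text(
        "\n".join(GROSS_TYPES) + "\n", encoding="utf-8"
    )
    print(f"wrote gross_types.txt ({len(GROSS_TYPES)} labels)")


if __name__ == "__main__":
    main()
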