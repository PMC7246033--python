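"""Inspect the packaged 218-antibody panel.

Prints each functional category with its primary-antibody and
overlap-reference counts; the parenthesized overlaps are antibodies whose
measurement lives in another category.
"""

import iphplc as ip

catalog = ip.load_default_panel()
counts = ip.category_counts(catalog)

for category, (primary, overlap) in counts.items():
    suffix = f" ({overlap})" if overlap else ""
    print(f"{category:<38s} {primary:>3d}{suffix}")

total_p = sum(p for p, _ in counts.values())
total_o = sum(o for _, o in counts.values())
print(f"{'Total':<38s} {total_p:>3d} ({total_o})")
print("housekeeping:", ", ".join(catalog.housekeeping_names()))
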