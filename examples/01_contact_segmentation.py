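"""Segment a tactile stimulation series into contacts.

A contact is one maximal run of uninterrupted stimulation; every object
type overlapping anywhere inside the run is counted once for that contact,
no matter how many separate overlap episodes it has.
"""

from percross import count_contacts_by_type, segment_contacts
from percross.datasets import CONTACT_EXAMPLE

overlaps = {k: v for k, v in CONTACT_EXAMPLE.items() if k != "stim"}
contacts = segment_contacts(CONTACT_EXAMPLE["stim"], overlaps)

print("stim  :", CONTACT_EXAMPLE["stim"])
for name in ("avatar", "static", "shadow"):
    print(f"{name:<6}:", CONTACT_EXAMPLE[name])
print()
for c in contacts:
    print(f"contact steps [{c.start}, {c.end}): types {sorted(c.types)}")
print("counts per type:", count_contacts_by_type(contacts))
# Three runs of stimulation; the first two each involve the partner's avatar
# and the own static object, the last only the partner's shadow, so the
# per-type totals are avatar=2, static=2, shadow=1.
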