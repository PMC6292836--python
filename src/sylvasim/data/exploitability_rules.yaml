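# Exploitability rule table: maps the four ordinal terrain descriptors to
# one of the four exploitability levels.  Each descriptor takes one of the
# ordered categories below (best first).  The default rule is
# worst-category-dominates: the plot's level is the level attached to the
# worst category among its four descriptors.  The table is editable; the
# per-category level assignments below are the shipped defaults.
descriptors:
  slope:            # terrain slope
    categories: [flat, moderate, steep, extreme]
    levels:     [very-easy, easy, difficult, impossible]
  ruggedness:       # surface obstacles / rockiness
    categories: [smooth, uneven, rough, blocked]
    levels:     [very-easy, easy, difficult, impossible]
  distance_to_ride: # skidding distance to the nearest forest ride
    categories: [adjacent, near, far, remote]
    levels:     [very-easy, easy, difficult, impossible]
  carrying_capacity: # bearing capacity of the ground for machinery
    categories: [firm, seasonal, soft, none]
    levels:     [very-easy, easy, difficult, impossible]
rule: worst-dominates
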