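"""Advection travel times from the five ice locations to Erebus Bay.

Builds the along-coast great-circle paths from the printed coordinates and
converts them to whole-day phytoplankton travel times at the three published
current velocities.  The minimum across sources (the Southwest location) is
5 days at the slow current, 3 at the intermediate and fast currents.
"""

from icepulse.ice_phenology import SOURCE_CHAIN, advection_duration, path_km

print(f"{'source':<12} {'direct km':>9} {'coastal km':>10}  days @6.5 @10.3 @12")
for name in SOURCE_CHAIN:
    d_direct = path_km(name, "direct")
    d_coast = path_km(name, "coastal")
    days = [advection_duration(d_coast, v) for v in (6.5, 10.3, 12.0)]
    print(f"{name:<12} {d_direct:9.1f} {d_coast:10.1f}       "
          f"{days[0]:3d}  {days[1]:3d} {days[2]:3d}")

print("\nEach row: distance to the study site and whole-day travel time per "
      "current velocity; the closest source sets the earliest possible "
      "resource-pulse arrival after its ice break-out.")
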