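"""The nine surveyed resource-collection activities and their resource class.

Plant-based activities target wood and non-timber plant products collected
near settlements; animal-based activities (hunting, fishing, honey
harvesting) involve substantially longer trips.  Default trip-distance
medians reflect the reported pattern: plant activities span 2 km (firewood)
to 8 km (house construction, handicraft making), animal activities sit at
15 km.
"""

from __future__ import annotations

PLANT = "plant"
ANIMAL = "animal"

#: activity -> (resource class, default median trip distance in km)
ACTIVITIES: dict[str, tuple[str, float]] = {
    "firewood cutting": (PLANT, 2.0),
    "fruit gathering": (PLANT, 4.0),
    "charcoal production": (PLANT, 5.0),
    "carpentry": (PLANT, 6.0),
    "house construction": (PLANT, 8.0),
    "handicraft making": (PLANT, 8.0),
    "hunting": (ANIMAL, 15.0),
    "fishing": (ANIMAL, 15.0),
    "honey harvesting": (ANIMAL, 15.0),
}

RESOURCE_CLASSES = (PLANT, ANIMAL)


def resource_class_of(activity: str) -> str:
    try:
        return ACTIVITIES[activity][0]
    except KeyError:
        raise ValueError(f"unknown activity: {activity!r}") from None


def activities_of_class(resource_class: str) -> list[str]:
    if resource_class not in RESOURCE_CLASSES:
        raise ValueError(f"unknown resource class: {resource_class!r}")
    return [a for a, (c, _) in ACTIVITIES.items() if c == resource_class]
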