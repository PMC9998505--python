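"""Independent brute-force oracles shared by test modules."""

import numpy as np


def brute_force_components(mask):
    """Flood-fill connected components under face connectivity."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for ax in range(mask.ndim):
                for step in (-1, 1):
                    nxt = list(cur)
                    nxt[ax] += step
                    nxt = tuple(nxt)
                    if all(0 <= nxt[d] < mask.shape[d]
                           for d in range(mask.ndim)) \
                            and mask[nxt] and not seen[nxt]:
                        seen[nxt] = True
                        stack.append(nxt)
        comps.append(sorted(comp))
    return sorted(comps)
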