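# File formats

All four record types are plain CSV with a header row, UTF-8, one
directory per dataset. Times are an ISO date plus seconds within the
observation session (float). Multi-valued fields pack items with `;`
between items and `|` within an item; those characters are therefore
forbidden in individual ids. Empty string encodes "absent".

## roster.csv

| column | type | notes |
|---|---|---|
| id | string | unique within the dataset |
| name | string | display name; defaults to id |
| sex | `F` / `M` | |
| age_years | float ≥ 0 | |
| age_class | `adult` / `adolescent` / `juvenile` / `infant` | infants load but are excluded from analyses by filter |
| rearing | `mother_reared` / `orphan` | |
| mother_id | id or empty | must be a female in the same group |
| group_id | string | |

## conflicts.csv

| column | type | notes |
|---|---|---|
| conflict_id | int | unique |
| group_id | string | |
| date | ISO date | |
| time_s | float | conflict end, seconds within session |
| victim_id / aggressor_id | id | distinct |
| context | `feed`, `rest`, `play`, `object_food_competition`, `arrival`, `anticipating_feed`, `social_tension_display` | |
| intensity | int 1–6 | threat … injurious attack |
| bystanders | packed `id|band;id|band` | band ∈ `lt5m`,`5to10m`,`gt10m`; opponents excluded |
| redirection_target | id or empty | must be a listed bystander |

## follows.csv (long format)

Each follow owns one `record=follow` row carrying the metadata, followed
by its event rows (same metadata columns repeated):

| column | notes |
|---|---|
| follow_id, conflict_id, kind (`PC`/`MC`), focal_id, date, start_time_s, duration_s | follow metadata (every row) |
| record | `follow` / `bystander` / `contact` / `self_directed` |
| time_s | event latency from follow start (contact, self_directed) |
| actor_id | bystander id, or contact initiator |
| partner_id | contact recipient |
| behavior | affiliative behavior for contacts (`embrace`, `sociosexual`, `touch`, `groom`, `contact_sit`, `play`, `hold`, `pat`, `inspect`); `scratch_bout` / `groom_interval` for self-directed rows |
| event_duration_s | groom-interval duration; empty otherwise |
| proximity_band | for bystander rows |

A PC starts at its conflict's end (same date, same `time_s`). Each
conflict has at most one PC and one MC.

## scans.csv

| column | notes |
|---|---|
| scan_id, group_id, date, time_s | scans ≥ 10 min apart within a session |
| present_ids | `;`-joined ids |
| engaged | packed `a|b|behavior;…`, behavior ∈ `groom`, `contact_sit`, `arms_reach`, `play`, `sexual_contact`; pairs ⊆ present |

`pcmckit validate --dataset DIR` checks all schemas plus referential
integrity, and reports which conflicts were excluded for lacking a valid
matched control.
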