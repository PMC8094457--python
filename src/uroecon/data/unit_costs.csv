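item,unit,unit_cost,price_year
theatre_minute,per-minute,20.00,2016
staff_minute,per-minute,3.00,2017
bed_day,per-day,300.00,2017
consumable_pack,per-item,150.00,2016
followup_contact,per-contact,45.00,2017
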