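patient_id,self_reported,system_recorded,device_logged,elapsed_days,notifications_expected,notifications_received,flags,notes
P1,13,13,13,14,10,10,,even split of a two-patient 26/26 aggregate (synthetic split)
P2,13,13,13,14,10,10,,even split of a two-patient 26/26 aggregate (synthetic split)
P3,12,11,11,14,9,9,,member of a two-patient ~90% (20/22) aggregate; split forced by totals
P4,10,9,34,14,,,spurious_device,member of a two-patient ~90% (20/22) aggregate; device counter spuriously high
P5,8,6,135,7,,,spurious_device,device counter spuriously high
P6,13,3,11,14,,,,notification sender not scheduled during participation
P7,4,0,0,7,,,never_sync,device never synced; stock software logged no sessions
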