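center_id,year,month,patient_status,tumor_group,sex,stage,count
C01,2019,1,new,all,all,all,316
C01,2019,2,new,all,all,all,257
C01,2019,3,new,all,all,all,302
C01,2019,4,new,all,all,all,314
C01,2019,5,new,all,all,all,291
C01,2019,6,new,all,all,all,281
C01,2019,7,new,all,all,all,310
C01,2020,1,new,all,all,all,300
C01,2020,2,new,all,all,all,274
C01,2020,3,new,all,all,all,278
C01,2020,4,new,all,all,all,201
C01,2020,5,new,all,all,all,211
C01,2020,6,new,all,all,all,265
C01,2020,7,new,all,all,all,287
C02,2019,1,new,all,all,all,234
C02,2019,2,new,all,all,all,253
C02,2019,3,new,all,all,all,297
C02,2019,4,new,all,all,all,255
C02,2019,5,new,all,all,all,260
C02,2019,6,new,all,all,all,277
C02,2019,7,new,all,all,all,297
C02,2020,1,new,all,all,all,310
C02,2020,2,new,all,all,all,244
C02,2020,3,new,all,all,all,304
C02,2020,4,new,all,all,all,179
C02,2020,5,new,all,all,all,223
C02,2020,6,new,all,all,all,253
C02,2020,7,new,all,all,all,280
C03,2019,1,new,all,all,all,379
C03,2019,2,new,all,all,all,326
C03,2019,3,new,all,all,all,392
C03,2019,4,new,all,all,all,338
C03,2019,5,new,all,all,all,408
C03,2019,6,new,all,all,all,340
C03,2019,7,new,all,all,all,395
C03,2020,1,new,all,all,all,391
C03,2020,2,new,all,all,all,368
C03,2020,3,new,all,all,all,378
C03,2020,4,new,all,all,all,299
C03,2020,5,new,all,all,all,320
C03,2020,6,new,all,all,all,357
C03,2020,7,new,all,all,all,334
C04,2019,1,new,all,all,all,224
C04,2019,2,new,all,all,all,228
C04,2019,3,new,all,all,all,234
C04,2019,4,new,all,all,all,247
C04,2019,5,new,all,all,all,209
C04,2019,6,new,all,all,all,208
C04,2019,7,new,all,all,all,243
C04,2020,1,new,all,all,all,281
C04,2020,2,new,all,all,all,255
C04,2020,3,new,all,all,all,246
C04,2020,4,new,all,all,all,194
C04,2020,5,new,all,all,all,208
C04,2020,6,new,all,all,all,208
C04,2020,7,new,all,all,all,134
C05,2019,1,new,all,all,all,284
C05,2019,2,new,all,all,all,240
C05,2019,3,new,all,all,all,279
C05,2019,4,new,all,all,all,309
C05,2019,5,new,all,all,all,253
C05,2019,6,new,all,all,all,241
C05,2019,7,new,all,all,all,326
C05,2020,1,new,all,all,all,307
C05,2020,2,new,all,all,all,256
C05,2020,3,new,all,all,all,266
C05,2020,4,new,all,all,all,210
C05,2020,5,new,all,all,all,218
C05,2020,6,new,all,all,all,238
C05,2020,7,new,all,all,all,250
C06,2019,1,new,all,all,all,274
C06,2019,2,new,all,all,all,281
C06,2019,3,new,all,all,all,286
C06,2019,4,new,all,all,all,258
C06,2019,5,new,all,all,all,285
C06,2019,6,new,all,all,all,281
C06,2019,7,new,all,all,all,336
C06,2020,1,new,all,all,all,294
C06,2020,2,new,all,all,all,304
C06,2020,3,new,all,all,all,287
C06,2020,4,new,all,all,all,291
C06,2020,5,new,all,all,all,238
C06,2020,6,new,all,all,all,265
C06,2020,7,new,all,all,all,278
C07,2019,1,new,all,all,all,513
C07,2019,2,new,all,all,all,471
C07,2019,3,new,all,all,all,549
C07,2019,4,new,all,all,all,534
C07,2019,5,new,all,all,all,493
C07,2019,6,new,all,all,all,436
C07,2019,7,new,all,all,all,574
C07,2020,1,new,all,all,all,509
C07,2020,2,new,all,all,all,525
C07,2020,3,new,all,all,all,482
C07,2020,4,new,all,all,all,389
C07,2020,5,new,all,all,all,365
C07,2020,6,new,all,all,all,494
C07,2020,7,new,all,all,all,502
C08,2019,1,new,all,all,all,415
C08,2019,2,new,all,all,all,356
C08,2019,3,new,all,all,all,350
C08,2019,4,new,all,all,all,359
C08,2019,5,new,all,all,all,352
C08,2019,6,new,all,all,all,337
C08,2019,7,new,all,all,all,394
C08,2020,1,new,all,all,all,399
C08,2020,2,new,all,all,all,379
C08,2020,3,new,all,all,all,401
C08,2020,4,new,all,all,all,298
C08,2020,5,new,all,all,all,287
C08,2020,6,new,all,all,all,359
C08,2020,7,new,all,all,all,345
C09,2019,1,new,all,all,all,676
C09,2019,2,new,all,all,all,564
C09,2019,3,new,all,all,all,589
C09,2019,4,new,all,all,all,581
C09,2019,5,new,all,all,all,598
C09,2019,6,new,all,all,all,555
C09,2019,7,new,all,all,all,622
C09,2020,1,new,all,all,all,587
C09,2020,2,new,all,all,all,600
C09,2020,3,new,all,all,all,625
C09,2020,4,new,all,all,all,395
C09,2020,5,new,all,all,all,438
C09,2020,6,new,all,all,all,455
C09,2020,7,new,all,all,all,490
C10,2019,1,new,all,all,all,345
C10,2019,2,new,all,all,all,321
C10,2019,3,new,all,all,all,328
C10,2019,4,new,all,all,all,314
C10,2019,5,new,all,all,all,334
C10,2019,6,new,all,all,all,298
C10,2019,7,new,all,all,all,350
C10,2020,1,new,all,all,all,344
C10,2020,2,new,all,all,all,339
C10,2020,3,new,all,all,all,285
C10,2020,4,new,all,all,all,279
C10,2020,5,new,all,all,all,244
C10,2020,6,new,all,all,all,324
C10,2020,7,new,all,all,all,346
C11,2019,1,new,all,all,all,766
C11,2019,2,new,all,all,all,750
C11,2019,3,new,all,all,all,702
C11,2019,4,new,all,all,all,708
C11,2019,5,new,all,all,all,764
C11,2019,6,new,all,all,all,682
C11,2019,7,new,all,all,all,752
C11,2020,1,new,all,all,all,785
C11,2020,2,new,all,all,all,695
C11,2020,3,new,all,all,all,664
C11,2020,4,new,all,all,all,520
C11,2020,5,new,all,all,all,461
C11,2020,6,new,all,all,all,595
C11,2020,7,new,all,all,all,686
C12,2019,1,new,all,all,all,298
C12,2019,2,new,all,all,all,245
C12,2019,3,new,all,all,all,283
C12,2019,4,new,all,all,all,267
C12,2019,5,new,all,all,all,269
C12,2019,6,new,all,all,all,304
C12,2019,7,new,all,all,all,284
C12,2020,1,new,all,all,all,328
C12,2020,2,new,all,all,all,274
C12,2020,3,new,all,all,all,242
C12,2020,4,new,all,all,all,228
C12,2020,5,new,all,all,all,259
C12,2020,6,new,all,all,all,238
C12,2020,7,new,all,all,all,288
C13,2019,1,new,all,all,all,424
C13,2019,2,new,all,all,all,362
C13,2019,3,new,all,all,all,329
C13,2019,4,new,all,all,all,330
C13,2019,5,new,all,all,all,307
C13,2019,6,new,all,all,all,321
C13,2019,7,new,all,all,all,380
C13,2020,1,new,all,all,all,389
C13,2020,2,new,all,all,all,312
C13,2020,3,new,all,all,all,250
C13,2020,4,new,all,all,all,241
C13,2020,5,new,all,all,all,255
C13,2020,6,new,all,all,all,337
C13,2020,7,new,all,all,all,353
C14,2019,1,new,all,all,all,613
C14,2019,2,new,all,all,all,538
C14,2019,3,new,all,all,all,583
C14,2019,4,new,all,all,all,583
C14,2019,5,new,all,all,all,586
C14,2019,6,new,all,all,all,556
C14,2019,7,new,all,all,all,642
C14,2020,1,new,all,all,all,606
C14,2020,2,new,all,all,all,572
C14,2020,3,new,all,all,all,609
C14,2020,4,new,all,all,all,563
C14,2020,5,new,all,all,all,490
C14,2020,6,new,all,all,all,551
C14,2020,7,new,all,all,all,600
C15,2019,1,new,all,all,all,438
C15,2019,2,new,all,all,all,380
C15,2019,3,new,all,all,all,365
C15,2019,4,new,all,all,all,382
C15,2019,5,new,all,all,all,381
C15,2019,6,new,all,all,all,354
C15,2019,7,new,all,all,all,415
C15,2020,1,new,all,all,all,399
C15,2020,2,new,all,all,all,366
C15,2020,3,new,all,all,all,415
C15,2020,4,new,all,all,all,339
C15,2020,5,new,all,all,all,308
C15,2020,6,new,all,all,all,392
C15,2020,7,new,all,all,all,371
C16,2019,1,new,all,all,all,181
C16,2019,2,new,all,all,all,176
C16,2019,3,new,all,all,all,198
C16,2019,4,new,all,all,all,183
C16,2019,5,new,all,all,all,180
C16,2019,6,new,all,all,all,176
C16,2019,7,new,all,all,all,198
C16,2020,1,new,all,all,all,196
C16,2020,2,new,all,all,all,194
C16,2020,3,new,all,all,all,191
C16,2020,4,new,all,all,all,123
C16,2020,5,new,all,all,all,127
C16,2020,6,new,all,all,all,208
C16,2020,7,new,all,all,all,214
C17,2019,1,new,all,all,all,496
C17,2019,2,new,all,all,all,435
C17,2019,3,new,all,all,all,475
C17,2019,4,new,all,all,all,492
C17,2019,5,new,all,all,all,488
C17,2019,6,new,all,all,all,466
C17,2019,7,new,all,all,all,506
C17,2020,1,new,all,all,all,500
C17,2020,2,new,all,all,all,488
C17,2020,3,new,all,all,all,462
C17,2020,4,new,all,all,all,335
C17,2020,5,new,all,all,all,367
C17,2020,6,new,all,all,all,413
C17,2020,7,new,all,all,all,440
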