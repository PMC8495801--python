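{
  "latitude": 24.84,
  "longitude": 55.36,
  "utc_offset": 4.0,
  "samples": [
    {
      "local_time": "2018-01-15T07:30",
      "elevation_deg": 4.315,
      "sunrise_local": "2018-01-15T07:05:05"
    },
    {
      "local_time": "2018-03-20T12:30",
      "elevation_deg": 65.017,
      "sunrise_local": "2018-03-20T06:22:54"
    },
    {
      "local_time": "2018-06-21T05:45",
      "elevation_deg": 2.263,
      "sunrise_local": "2018-06-21T05:29:51"
    },
    {
      "local_time": "2018-09-23T18:10",
      "elevation_deg": 0.12,
      "sunrise_local": "2018-09-23T06:07:24"
    },
    {
      "local_time": "2019-02-10T00:30",
      "elevation_deg": -79.7,
      "sunrise_local": "2019-02-10T06:56:23"
    },
    {
      "local_time": "2019-05-05T13:00",
      "elevation_deg": 76.451,
      "sunrise_local": "2019-05-05T05:40:41"
    },
    {
      "local_time": "2019-08-17T20:00",
      "elevation_deg": -15.47,
      "sunrise_local": "2019-08-17T05:53:21"
    },
    {
      "local_time": "2019-11-30T06:40",
      "elevation_deg": -1.905,
      "sunrise_local": "2019-11-30T06:45:08"
    },
    {
      "local_time": "2020-03-20T12:30",
      "elevation_deg": 65.219,
      "sunrise_local": "2020-03-20T06:22:22"
    },
    {
      "local_time": "2020-07-04T03:15",
      "elevation_deg": -26.644,
      "sunrise_local": "2020-07-04T05:33:57"
    }
  ]
}
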